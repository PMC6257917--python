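"""Published operating characteristics of the 1993-2009 GAB aerial surveys.

These tables summarise the two-spotter era of the scientific aerial survey
for juvenile southern bluefin tuna in the Great Australian Bight: the
spotter-pair roster by year and plane, annual effort and sighting summaries,
the reported school-size calibration effects, the reported relative
sighting efficiencies of observer pairs, and the reported environmental
coefficient estimates of the standardization models.  They serve two roles:

* as the default operating point of the synthetic survey generator, so that
  simulated surveys resemble the real programme; and
* as reference inputs for desk-scale recomputation (e.g. sightings-per-100-nm
  rates from the printed distance and count columns).

Observer codes are the anonymised numeric codes used by the survey
programme.  Trainee spotters (codes 1, 2, 6, 9) did not estimate school
biomass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SPOTTER_PAIRS_BY_YEAR",
    "TRAINEE_OBSERVERS",
    "ANNUAL_SUMMARY",
    "OBSERVER_SIZE_EFFECTS",
    "PAIR_EFFICIENCIES",
    "BPS_SST_COEF",
    "SPM_ENV_COEFS",
    "TWEEDIE_P",
    "TWEEDIE_PHI",
    "derive_individual_spotting_rates",
]

#: spotter pairs (pilot, spotter) that flew in each survey year, all planes pooled
SPOTTER_PAIRS_BY_YEAR: dict[int, tuple[tuple[int, int], ...]] = {
    1993: ((5, 7), (5, 4), (5, 8)),
    1994: ((5, 7), (5, 4), (8, 7), (8, 4)),
    1995: ((5, 7), (5, 4), (5, 3), (8, 7), (8, 4)),
    1996: ((5, 7), (5, 3), (4, 7), (4, 3)),
    1997: ((5, 7), (5, 3), (4, 7), (4, 3)),
    1998: ((5, 7), (5, 3), (4, 7), (4, 3)),
    1999: ((10, 6), (10, 9), (4, 6), (4, 9)),
    2000: ((10, 1), (10, 2), (4, 1), (4, 2)),
    2005: ((4, 11),),
    2006: ((4, 11),),
    2007: ((4, 11), (4, 3)),
    2008: ((5, 11), (5, 3)),
    2009: ((5, 11), (5, 3)),
}

#: trainee spotters: flew in 1999-2000, made sightings but no biomass estimates
TRAINEE_OBSERVERS: frozenset[int] = frozenset({1, 2, 6, 9})

#: annual summary of survey data: total distance searched (nm), number of
#: sightings, sightings per 100 nm, mean/max adjusted biomass (t) per sighting,
#: mean/max schools per sighting
ANNUAL_SUMMARY = pd.DataFrame(
    [
        (1993, 7603, 129, 1.70, 94.5, 1426, 3.9, 76),
        (1994, 15180, 160, 1.05, 87.2, 631, 3.3, 23),
        (1995, 14573, 165, 1.13, 121.0, 1389, 3.5, 38),
        (1996, 12284, 110, 0.90, 144.4, 1763, 4.0, 46),
        (1997, 8813, 101, 1.15, 89.5, 852, 3.2, 18),
        (1998, 8550, 104, 1.22, 92.6, 1895, 2.2, 21),
        (1999, 7555, 50, 0.66, 59.5, 993, 2.5, 21),
        (2000, 6775, 76, 1.12, 62.6, 414, 2.6, 17),
        (2005, 5968, 79, 1.32, 74.1, 398, 2.4, 17),
        (2006, 5150, 43, 0.83, 91.4, 958, 2.0, 8),
        (2007, 4872, 41, 0.84, 84.0, 410, 2.6, 11),
        (2008, 7462, 121, 1.62, 65.6, 614, 3.5, 24),
        (2009, 8101, 145, 1.79, 53.9, 896, 2.5, 22),
    ],
    columns=["year", "distance_nm", "n_sightings", "rate_per_100nm",
             "mean_biomass_t", "max_biomass_t", "mean_schools", "max_schools"],
)

#: reported multiplicative school-size effects (beta) relative to observer 5
#: (beta_5 == 1); beta < 1 means systematic underestimation.
OBSERVER_SIZE_EFFECTS: dict[int, float] = {
    3: 0.81, 4: 1.00, 5: 1.00, 7: 0.97, 8: 0.95, 11: 1.10,
}

#: reported sighting efficiency of each (pilot, spotter) pair relative to the
#: most efficient pair (5, 11)
PAIR_EFFICIENCIES: dict[tuple[int, int], float] = {
    (4, 1): 0.76, (10, 2): 0.80, (10, 1): 0.75, (4, 2): 0.81,
    (5, 7): 0.87, (5, 3): 0.89, (4, 3): 0.86, (4, 7): 0.85,
    (10, 6): 0.68, (10, 9): 0.63, (4, 9): 0.63, (4, 6): 0.68,
    (5, 8): 0.88, (8, 4): 0.86, (5, 4): 0.93, (8, 7): 0.82,
    (4, 11): 0.96, (5, 11): 1.00,
}

#: reported linear SST coefficient of the biomass-per-sighting model (per degC)
BPS_SST_COEF: float = 0.326

#: reported linear environmental coefficients of the sightings-per-mile model
SPM_ENV_COEFS: dict[str, float] = {
    "sst": 0.328,      # per degC
    "wind": -0.305,    # per knot
    "haze": -0.137,    # per haze level (0-3)
    "swell": -0.193,   # per swell level (0-3)
    "shadow": -0.053,  # per octa of sea shadow (0-8)
}

#: reported Tweedie power and dispersion of the sightings-per-mile model
TWEEDIE_P: float = 1.13
TWEEDIE_PHI: float = 1.78


def derive_individual_spotting_rates(
    pair_eff: dict[tuple[int, int], float] | None = None,
) -> dict[int, float]:
    """Back out individual spotting rates consistent with the pair table.

    A pair's efficiency is modelled as the sum of its members' individual
    spotting rates, normalised so the best pair scores one.  Solving the
    (overdetermined) linear system ``e_pilot + e_spotter = pair_eff`` by least
    squares gives per-observer rates used by the simulator to attribute each
    sighting to the spotter who made it and to construct pair offsets.
    """
    pair_eff = dict(PAIR_EFFICIENCIES if pair_eff is None else pair_eff)
    observers = sorted({o for p in pair_eff for o in p})
    idx = {o: i for i, o in enumerate(observers)}
    A = np.zeros((len(pair_eff), len(observers)))
    b = np.zeros(len(pair_eff))
    for r, ((pilot, spotter), eff) in enumerate(sorted(pair_eff.items())):
        A[r, idx[pilot]] += 1.0
        A[r, idx[spotter]] += 1.0
        b[r] = eff
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    sol = np.clip(sol, 0.05, None)  # spotting rates are strictly positive
    return {o: float(sol[idx[o]]) for o in observers}
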