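"""Published summary data for eleven *Rana parvipalmata* populations.

Per-population values from a field study of tadpole thermal tolerance on a
Cantabrian elevation gradient (40–1835 m a.s.l.): critical thermal limits
assayed after acclimation at 20 degC (n, mean, SE), macroclimate (TMAX,
TMIN, SR) and pond-microclimate (tmax, tmin, sr, dr) temperature summaries
over each population's larval period, the derived warming/cooling
tolerances (WT, wt, CT, ct), and acclimation-treatment CTmax means for the
five populations used in the plasticity experiment.

These are desk-scale inputs: the arithmetic identities (WT = CTmax - TMAX
etc.), the elevation regressions, the paired comparisons of macro vs
micro margins, and the plasticity/ARR metrics can all be recomputed from
them. The raw individual-level data are not distributed here.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "field_study_table",
    "acclimation_ctmax_means",
    "ACCLIMATION_TEMPS_C",
]

ACCLIMATION_TEMPS_C = (6.0, 13.0, 20.0, 27.0)

# population, elevation_m, CTmax (n, mean, se), CTmin (n, mean, se),
# TMAX, tmax, TMIN, tmin, SR, sr, dr, WT, wt, CT, ct
_FIELD_ROWS = [
    ("Llagusecu",   1835, 14, 37.0, 0.1, 14, -1.9, 0.1, 14.1, 29.7,  1.4, 0.5, 5.4, 29.2,  5.5, 22.9,  7.3, 3.3,  2.4),
    ("Senales",     1635, 14, 36.8, 0.1, 16, -1.8, 0.1, 15.6, 22.6, -1.2, 4.0, 7.0, 18.6,  4.9, 21.2, 14.2, 0.6,  5.8),
    ("Aliva",       1418, 14, 37.5, 0.1, 16, -1.9, 0.1, 16.3, 24.5, -0.5, 4.3, 6.3, 20.2,  6.5, 21.2, 13.0, 1.4,  6.2),
    ("Pandebano",   1219, 16, 36.7, 0.1, 16, -1.9, 0.1, 15.4, 28.9, -0.8, 0.6, 6.9, 28.3,  7.8, 21.3,  7.8, 1.1,  2.5),
    ("Pandecarmen", 1106, 16, 37.0, 0.1, 16, -1.8, 0.1, 16.8, 33.0, -0.3, 0.2, 7.5, 34.6, 13.1, 20.2,  4.0, 1.5,  2.0),
    ("Fana",         950, 16, 36.5, 0.1, 16, -1.3, 0.1, 17.2, 29.3, -0.2, 1.5, 7.4, 27.8,  8.9, 19.3,  7.2, 1.1,  2.8),
    ("Cortegueros",  650, 16, 36.8, 0.1, 12, -1.6, 0.1, 18.9, 28.4,  1.8, 1.0, 7.5, 27.4,  6.2, 17.9,  8.4, 3.3,  2.6),
    ("Viango",       480, 16, 37.1, 0.1, 15, -2.1, 0.2, 19.3, 25.6,  1.9, 2.4, 7.0, 23.2,  5.0, 17.8, 11.5, 4.0,  4.5),
    ("Color",        380, 16, 36.9, 0.1, 16, -2.3, 0.1, 19.1, 22.5,  3.0, 3.8, 6.7, 18.7,  1.0, 17.8, 14.4, 5.3,  6.1),
    ("Nueva",        140, 16, 36.8, 0.1, 13, -1.9, 0.1, 21.1, 15.7,  5.0, 6.4, 7.1,  9.3,  1.7, 15.7, 21.1, 6.9,  8.3),
    ("Puron",         36, 16, 36.4, 0.1, 16, -0.9, 0.1, 21.7, 11.4,  4.7, 9.9, 7.6,  1.5,  0.4, 14.7, 25.0, 5.6, 10.8),
]

_FIELD_COLUMNS = [
    "population", "elevation_m",
    "ctmax_n", "ctmax_mean", "ctmax_se",
    "ctmin_n", "ctmin_mean", "ctmin_se",
    "TMAX", "tmax", "TMIN", "tmin", "SR", "sr", "dr",
    "WT", "wt", "CT", "ct",
]


def field_study_table() -> pd.DataFrame:
    """The 11-population summary table, ordered from high to low elevation.

    Columns: elevation (m), CTmax and CTmin assay summaries (n, mean, SE,
    degC), macro/micro climate summaries over the larval window (degC)
    and the four published vulnerability margins. Note the published sr
    column equals tmax - tmin for all rows except Pandecarmen; the
    published values are reproduced verbatim.
    """
    return pd.DataFrame(_FIELD_ROWS, columns=_FIELD_COLUMNS)


# Acclimation experiment: CTmax mean (degC) and SE by treatment for the five
# populations assayed at 6 / 13 / 20 / 27 degC; n per cell.
_ACCLIM_ROWS = [
    # population, acclimation_c, n, mean, se
    ("Nueva",        6.0, 11, 36.06, 0.13),
    ("Nueva",       13.0, 12, 36.37, 0.08),
    ("Nueva",       20.0, 16, 36.84, 0.08),
    ("Nueva",       27.0, 16, 38.21, 0.05),
    ("Cortegueros",  6.0, 16, 35.91, 0.10),
    ("Cortegueros", 13.0, 16, 36.16, 0.09),
    ("Cortegueros", 20.0, 16, 36.76, 0.09),
    ("Cortegueros", 27.0, 16, 38.11, 0.11),
    ("Pandecarmen",  6.0, 17, 35.64, 0.07),
    ("Pandecarmen", 13.0, 17, 36.02, 0.09),
    ("Pandecarmen", 20.0, 16, 37.04, 0.11),
    ("Pandecarmen", 27.0, 17, 38.30, 0.09),
    ("Aliva",        6.0, 15, 36.21, 0.14),
    ("Aliva",       13.0, 14, 36.65, 0.08),
    ("Aliva",       20.0, 14, 37.46, 0.11),
    ("Aliva",       27.0, 12, 38.32, 0.11),
    ("Llagusecu",    6.0, 14, 36.26, 0.10),
    ("Llagusecu",   13.0, 14, 36.53, 0.10),
    ("Llagusecu",   20.0, 14, 37.03, 0.12),
    ("Llagusecu",   27.0, 14, 38.43, 0.11),
]


def acclimation_ctmax_means() -> pd.DataFrame:
    """CTmax treatment means for the five acclimation-experiment populations.

    Columns: population, acclimation_c, n, mean, se. The published
    plasticity row (27 vs 6 degC difference) and ARR rows are derivable
    from these means; the Pandecarmen plasticity value was printed as
    2.70 although its means differ by 2.66 (unrounded sources upstream).
    """
    return pd.DataFrame(
        _ACCLIM_ROWS, columns=["population", "acclimation_c", "n", "mean", "se"]
    )
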