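"""Stress intensity and per-genotype tolerance indices.

Given paired replicate-mean yields (Ypi under the normal sowing, Ysi
under the stress sowing of the same season) the module computes the
population stress intensity

    SI = 1 - Ȳs/Ȳp

and seven per-genotype indices:

    STI  = Ypi·Ysi / Ȳp²          (Fernandez stress tolerance index)
    TOL  = Ypi − Ysi              (tolerance, g/plot)
    GMP  = √(Ypi·Ysi)             (geometric mean productivity, g/plot)
    MP   = (Ypi + Ysi)/2          (mean productivity, g/plot)
    HARM = 2·Ypi·Ysi/(Ypi + Ysi)  (harmonic mean productivity, g/plot)
    SSI  = (1 − Ysi/Ypi)/SI       (Fischer–Maurer susceptibility index)
    YSI  = Ysi/Ypi                (yield stability index)

The STI denominator is the squared population mean Ȳp², not the
per-genotype Ypi² (with Ypi² the index would collapse to a rescaled
YSI).  SSI uses the Fischer–Maurer form, which makes it an exactly
decreasing affine map of YSI: YSI + SI·SSI = 1, hence the textbook
−1.00 correlation between the two columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import INDEX_COLUMNS, IndexTable, YieldPairTable


class StressIndexError(ValueError):
    """Domain error in index computation (e.g. SI = 0 with SSI requested)."""


def stress_intensity(ybar_p: float, ybar_s: float) -> float:
    """Population stress intensity SI = 1 − Ȳs/Ȳp.

    Parameters
    ----------
    ybar_p, ybar_s
        Across-genotype mean yields under the normal and stress
        environments (g/plot).  ``ybar_p`` must be positive.
    """
    if ybar_p <= 0:
        raise StressIndexError(f"mean normal yield must be positive, got {ybar_p}")
    return 1.0 - ybar_s / ybar_p


def compute_indices(pairs: YieldPairTable, allow_zero_si: bool = False) -> IndexTable:
    """Compute the nine-column index table from paired yields.

    Raises :class:`StressIndexError` when SI = 0 (no stress; SSI
    undefined) unless ``allow_zero_si`` is set, in which case SSI is
    reported as NaN.
    """
    df = pairs.data
    yp = df["Yp"].to_numpy(float)
    ys = df["Ys"].to_numpy(float)
    si = stress_intensity(pairs.ybar_p, pairs.ybar_s)

    if si == 0 and not allow_zero_si:
        raise StressIndexError(
            "stress intensity is 0 (mean stress yield equals mean normal yield); "
            "SSI is undefined — pass allow_zero_si=True to report NaN"
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        ssi = (1.0 - ys / yp) / si if si != 0 else np.full_like(yp, np.nan)

    out = pd.DataFrame(
        {
            "genotype": df["genotype"].to_numpy(),
            "Ys": ys,
            "Yp": yp,
            "STI": yp * ys / pairs.ybar_p**2,
            "TOL": yp - ys,
            "GMP": np.sqrt(yp * ys),
            "MP": (yp + ys) / 2.0,
            "HARM": 2.0 * yp * ys / (yp + ys),
            "SSI": ssi,
            "YSI": ys / yp,
        },
        columns=["genotype", *INDEX_COLUMNS],
    )
    return IndexTable(out, si=float(si), stress=pairs.stress)
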