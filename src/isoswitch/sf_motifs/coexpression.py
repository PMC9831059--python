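"""Co-expression filtering of splicing factors against isoform abundances."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from isoswitch.core_data import RelativeAbundance, TimeCourseMatrix
from isoswitch.switch_detection import adjust_pvalues

__all__ = ["sf_coexpression"]


def sf_coexpression(
    I: RelativeAbundance,
    sf_expression: TimeCourseMatrix,
    isoforms: Sequence[str] | None = None,
    r_cut: float = 0.7,
    alpha: float = 0.05,
    min_sf_tpm: float = 1.0,
) -> pd.DataFrame:
    """Correlate splicing-factor expression with switching-isoform abundance.

    Splicing factors must exceed ``min_sf_tpm`` at every time point
    (replicate means); pairs are retained when ``|r| > r_cut`` and the
    BH-adjusted correlation-test p-value is below ``alpha``.  Replicate-mean
    courses are used on both sides; zero-variance courses are skipped.

    Returns a DataFrame with columns splicing_factor, isoform, r, p, adj_p,
    retained.
    """
    if I.n_timepoints != sf_expression.n_timepoints:
        raise ValueError("time axes of isoform and splicing-factor data differ")
    iso_ids = list(isoforms) if isoforms is not None else list(I.transcript_ids)

    sf_courses = {}
    for sf in sf_expression.transcript_ids:
        course = sf_expression.course(sf).mean(axis=1)
        if np.all(course > min_sf_tpm):
            sf_courses[sf] = course

    rows = []
    for sf, x in sf_courses.items():
        if np.ptp(x) == 0:
            continue
        for iso in iso_ids:
            y = I.course(iso).mean(axis=1)
            if np.ptp(y) == 0:
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"splicing_factor": sf, "isoform": iso, "r": float(r), "p": float(p)})

    df = pd.DataFrame(rows, columns=["splicing_factor", "isoform", "r", "p"])
    if df.empty:
        df["adj_p"] = pd.Series(dtype=float)
        df["retained"] = pd.Series(dtype=bool)
        return df
    df["adj_p"] = adjust_pvalues(df["p"].to_numpy(), "BH")
    df["retained"] = (df["r"].abs() > r_cut) & (df["adj_p"] < alpha)
    return df
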