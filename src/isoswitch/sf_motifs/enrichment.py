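"""Motif enrichment: regulated vs. unregulated exon flanks."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from isoswitch.sf_motifs.flanks import ExonFlankSet
from isoswitch.sf_motifs.pssm import PSSMMotif, calibrate_threshold, pssm_scan

__all__ = ["motif_enrichment", "collect_hit_scores"]


def collect_hit_scores(
    sequences: Iterable[str], motif: PSSMMotif, threshold: float
) -> np.ndarray:
    """All position scores at or above ``threshold`` across the sequences."""
    hits: list[np.ndarray] = []
    for seq in sequences:
        if len(seq) < motif.length:
            continue
        scores = pssm_scan(seq, motif)
        hits.append(scores[scores >= threshold])
    return np.concatenate(hits) if hits else np.array([])


def motif_enrichment(
    lost: ExonFlankSet,
    gained: ExonFlankSet,
    unregulated: ExonFlankSet,
    motifs: Sequence[PSSMMotif],
    fpr: float = 0.01,
) -> pd.DataFrame:
    """One-sided Mann-Whitney enrichment of motif hits in regulated flanks.

    For every motif and exon boundary (5'/3'), above-threshold log-odds
    scores in the lost (resp. gained) flanks are compared against the
    unregulated flanks with a one-sided U-test (regulated greater).
    Comparisons lacking sequences or hits on either side get a NaN p-value.

    Returns a DataFrame with columns motif, boundary, comparison, n_regulated,
    n_unregulated, p.
    """
    rows = []
    for motif in motifs:
        threshold = motif.threshold
        if threshold is None:
            threshold = calibrate_threshold(motif, fpr)
        for boundary in ("5p", "3p"):
            attr = "five_prime" if boundary == "5p" else "three_prime"
            bg_scores = collect_hit_scores(getattr(unregulated, attr), motif, threshold)
            for flanks in (lost, gained):
                reg_seqs = getattr(flanks, attr)
                p = float("nan")
                reg_scores = collect_hit_scores(reg_seqs, motif, threshold)
                if (
                    len(reg_seqs) >= 2
                    and len(getattr(unregulated, attr)) >= 2
                    and len(reg_scores) > 0
                    and len(bg_scores) > 0
                ):
                    p = float(
                        stats.mannwhitneyu(
                            reg_scores, bg_scores, alternative="greater"
                        ).pvalue
                    )
                rows.append(
                    {
                        "motif": motif.name,
                        "boundary": boundary,
                        "comparison": f"{flanks.category}_vs_unregulated",
                        "n_regulated": len(reg_scores),
                        "n_unregulated": len(bg_scores),
                        "p": p,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["motif", "boundary", "comparison", "n_regulated", "n_unregulated", "p"],
    )
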