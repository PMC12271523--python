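"""Statistical comparison of biological and synthesized populations.

Feature distributions are centered and scaled against the reference
(reconstructed) population:

    V_norm(a) = (median(P_r) − V(a)) / σ(P_r),

so the reference median maps to 0 (note the median-minus-value
orientation).  Similarity of two samples is summarized by the Maximum
Visible Spread (MVS) score

    MVS(P, Q) = |median(P) − median(Q)| / max(spread(P), spread(Q)),

with spread half the 5th–95th percentile range.  Two populations are
flagged strongly similar (``**``) when MVS < 0.1 and non-random (``*``)
when MVS < 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from longax.projections import ProjectionMatrix, is_contra

__all__ = [
    "normalize",
    "mvs_score",
    "significance_flag",
    "FeatureComparison",
    "compare_feature",
    "compare_region_lengths",
    "projection_ratio",
    "STRONG_THRESHOLD",
    "NONRANDOM_THRESHOLD",
]

STRONG_THRESHOLD = 0.1
NONRANDOM_THRESHOLD = 0.5


def normalize(values, reference) -> np.ndarray:
    """Center to the reference median, scale by the reference SD.

    ``(median(P_r) − V) / σ(P_r)``; a value one reference SD *below* the
    median maps to +1.  Raises on zero reference SD.
    """
    ref = np.asarray(reference, float)
    sd = float(ref.std())
    if sd == 0:
        raise ValueError("reference sample has zero standard deviation")
    return (np.median(ref) - np.asarray(values, float)) / sd


def half_percentile_spread(sample, percentiles=(5.0, 95.0)) -> float:
    lo, hi = np.percentile(np.asarray(sample, float), percentiles)
    return float(hi - lo) / 2.0


def mvs_score(p, q, percentiles=(5.0, 95.0)) -> float:
    """Maximum Visible Spread score between two non-empty samples.

    0 for identical distributions; 1.0 when the medians differ by exactly
    one spread.  Degenerate samples (both spreads 0) give 0 on equal
    medians and +inf otherwise.  Symmetric and invariant under a common
    affine rescaling of both samples.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.size == 0 or q.size == 0:
        raise ValueError("mvs_score requires non-empty samples")
    spread = max(half_percentile_spread(p, percentiles),
                 half_percentile_spread(q, percentiles))
    gap = abs(float(np.median(p)) - float(np.median(q)))
    if spread == 0:
        return 0.0 if gap == 0 else float("inf")
    return gap / spread


def significance_flag(mvs: float) -> str:
    """'**' for MVS < 0.1 (strong), '*' for < 0.5 (non-random), else ''."""
    if mvs < STRONG_THRESHOLD:
        return "**"
    if mvs < NONRANDOM_THRESHOLD:
        return "*"
    return ""


@dataclass
class FeatureComparison:
    feature: str
    mvs: float
    flag: str
    reference_median: float
    test_median: float
    normalized_test: np.ndarray


def compare_feature(name: str, reference, test) -> FeatureComparison:
    """MVS + significance of one feature between reference and test samples."""
    score = mvs_score(reference, test)
    ref = np.asarray(reference, float)
    normed = (normalize(test, ref) if ref.std() > 0
              else np.zeros(np.asarray(test).shape))
    return FeatureComparison(
        feature=name,
        mvs=score,
        flag=significance_flag(score),
        reference_median=float(np.median(ref)),
        test_median=float(np.median(np.asarray(test, float))),
        normalized_test=normed,
    )


def compare_region_lengths(
    bio: ProjectionMatrix,
    synth: ProjectionMatrix,
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Per-region comparison of targeting and axonal length distributions.

    For each region: the fraction of axons terminating there in each
    population, the MVS score between the nonzero per-axon length
    distributions with its significance flag, and the total length per axon.
    """
    if regions is None:
        regions = sorted(set(bio.region_vocab) | set(synth.region_vocab))

    def column(mat: ProjectionMatrix, region: str) -> np.ndarray:
        try:
            j = mat.region_vocab.index(region)
        except ValueError:
            return np.zeros(mat.n_axons)
        return mat.lengths[:, j]

    rows = []
    for region in regions:
        lb = column(bio, region)
        ls = column(synth, region)
        frac_bio = float((lb > 0).mean()) if lb.size else 0.0
        frac_synth = float((ls > 0).mean()) if ls.size else 0.0
        lb_nz, ls_nz = lb[lb > 0], ls[ls > 0]
        if lb_nz.size and ls_nz.size:
            mvs = mvs_score(lb_nz, ls_nz)
        elif lb_nz.size == ls_nz.size == 0:
            mvs = 0.0
        else:
            mvs = float("inf")
        rows.append(
            {
                "region": region,
                "frac_terminating_bio": frac_bio,
                "frac_terminating_synth": frac_synth,
                "mvs_length": mvs,
                "flag": significance_flag(mvs),
                "total_length_per_axon_bio": float(lb.sum() / max(1, bio.n_axons)),
                "total_length_per_axon_synth": float(ls.sum() / max(1, synth.n_axons)),
                "n_bio_axons_terminating": int((lb > 0).sum()),
            }
        )
    return pd.DataFrame(rows)


def projection_ratio(matrix: ProjectionMatrix,
                     regions: list[str] | None = None) -> pd.DataFrame:
    """Proportion of axons targeting each region, with ipsi/contra split.

    The ratio of region *b* is (axons with at least one terminal in *b*) /
    (population size); contralateral vocabulary entries are reported
    separately with their base acronym and a hemisphere column.
    """
    if matrix.n_axons < 1:
        raise ValueError("empty population")
    if regions is None:
        regions = matrix.region_vocab
    rows = []
    for region in regions:
        try:
            j = matrix.region_vocab.index(region)
            ratio = float((matrix.terminals[:, j] > 0).mean())
        except ValueError:
            ratio = 0.0
        rows.append(
            {
                "region": region,
                "hemisphere": "contra" if is_contra(region) else "ipsi",
                "ratio": ratio,
            }
        )
    return pd.DataFrame(rows, columns=["region", "hemisphere", "ratio"])
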