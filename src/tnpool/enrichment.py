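"""Contingency-table enrichment with Monte-Carlo chi-square p-values.

Shared machinery for two analyses: enrichment of KEGG pathways among
zero-insertion genes (essentiality prediction) and among top
association-study hits. Both reduce to a family of 2x2 tables

    [[a, n_path - a], [A - a, (G - n_path) - (A - a)]]

where ``a`` counts focal-set members inside the pathway, ``n_path`` is the
pathway size, ``A`` the focal-set size and ``G`` the universe size. The
Pearson chi-square statistic is assessed by resampling tables with both
margins fixed — for a 2x2 this means drawing the top-left cell from a
hypergeometric distribution — and the p-value is (k + 1)/(B + 1) with k
the number of resampled statistics at least as large as the observed one,
so p is floored at 1/(B + 1) (0.0005 at B = 2000). Benjamini-Hochberg
adjustment is applied across the tested pathways.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "pearson_chi2",
    "monte_carlo_chi2_p",
    "enrichment_scan",
]

DEFAULT_B = 2000
DEFAULT_MIN_COUNT = 4

# relative slack when counting resampled statistics >= observed, so an exact
# tie (the observed table itself being redrawn) counts toward k, as in R's
# chisq.test(simulate.p.value=TRUE)
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class EnrichmentResult:
    """One pathway's enrichment test, mirroring the published table columns."""

    pathway: str
    a: int  # focal-set members in the pathway
    n_path: int  # pathway size in the universe
    statistic: float
    p: float
    fdr: float
    direction: str  # "essential"/"nonessential" or "enriched"/"depleted"


def pearson_chi2(table: np.ndarray) -> float:
    """Pearson chi-square statistic, no continuity correction.

    Degenerate tables (a zero margin) have no association to test and
    return 0.0.
    """
    t = np.asarray(table, dtype=float)
    if t.sum() == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 0.0
    return float(chi2_contingency(t, correction=False).statistic)


def _chi2_from_a(a: np.ndarray, r1: int, c1: int, n: int) -> np.ndarray:
    """Vectorized Pearson statistic for 2x2 tables parameterized by the
    top-left cell ``a`` with margins (r1, n-r1) x (c1, n-c1)."""
    a = np.asarray(a, dtype=float)
    e = np.array(
        [r1 * c1, r1 * (n - c1), (n - r1) * c1, (n - r1) * (n - c1)], dtype=float
    ) / n
    o = np.stack([a, r1 - a, c1 - a, n - r1 - c1 + a])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (o - e[:, None]) ** 2 / e[:, None]
    return np.nansum(terms, axis=0)


def monte_carlo_chi2_p(
    table: np.ndarray, B: int = DEFAULT_B, rng: np.random.Generator | int | None = None
) -> tuple[float, float]:
    """(statistic, Monte-Carlo p) for a 2x2 table with fixed margins.

    With both margins fixed the table is determined by its top-left cell,
    which under the null is hypergeometric; B such cells are drawn and
    p = (k + 1)/(B + 1).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    stat = pearson_chi2(t)
    n = int(t.sum())
    r1, c1 = int(t[0].sum()), int(t[:, 0].sum())
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return stat, 1.0
    a_sim = rng.hypergeometric(ngood=c1, nbad=n - c1, nsample=r1, size=B)
    sim = _chi2_from_a(a_sim, r1, c1, n)
    k = int(np.sum(sim >= stat * (1.0 - _TIE_RTOL)))
    return stat, (k + 1) / (B + 1)


def enrichment_scan(
    pathway_counts: pd.DataFrame,
    focal_total: int,
    universe_total: int,
    B: int = DEFAULT_B,
    min_count: int | None = DEFAULT_MIN_COUNT,
    min_count_on: str = "n_path",
    directions: tuple[str, str] = ("essential", "nonessential"),
    seed: int | np.random.Generator | None = 0,
    background_rate: float | None = None,
) -> list[EnrichmentResult]:
    """Run the Monte-Carlo chi-square over a family of pathways.

    Parameters
    ----------
    pathway_counts
        DataFrame indexed by pathway id with columns ``a`` (focal-set members
        in the pathway) and ``n_path`` (pathway size in the universe).
    focal_total, universe_total
        Sizes A and G of the focal set and the universe.
    min_count, min_count_on
        Pathways whose count in any of the named columns ("n_path", "a", or
        "both" for the pair) falls below ``min_count`` are excluded before
        testing, so they do not enter the FDR family.
    directions
        Labels for (focal fraction above background, below background).
    background_rate
        Baseline focal fraction for the direction call. Defaults to
        ``focal_total / universe_total``; pass the focal fraction of the
        pathway-annotated gene subset when the universe includes many
        unannotated genes, since pathway-annotated genes can have a focal
        rate quite different from the genome-wide one and the genome-wide
        baseline then mislabels pathways sitting between the two rates.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    df = pathway_counts
    bad = df.index[(df["n_path"] <= 0) | (df["a"] > df["n_path"])]
    if len(bad):
        raise ValueError(f"degenerate pathway counts for: {list(bad)}")
    if min_count is not None:
        cols = ["a", "n_path"] if min_count_on == "both" else [min_count_on]
        keep = np.logical_and.reduce([df[c] >= min_count for c in cols])
        df = df[keep]

    results: list[tuple[str, int, int, float, float, str]] = []
    for pathway, row in df.iterrows():
        a, n_path = int(row["a"]), int(row["n_path"])
        table = np.array(
            [
                [a, n_path - a],
                [focal_total - a, (universe_total - n_path) - (focal_total - a)],
            ]
        )
        stat, p = monte_carlo_chi2_p(table, B=B, rng=rng)
        baseline = (
            background_rate if background_rate is not None else focal_total / universe_total
        )
        direction = directions[0] if a / n_path > baseline else directions[1]
        results.append((str(pathway), a, n_path, stat, p, direction))

    if not results:
        return []
    pvals = np.array([r[4] for r in results])
    fdr = multipletests(pvals, method="fdr_bh")[1]
    out = [
        EnrichmentResult(pathway=pw, a=a, n_path=np_, statistic=stat, p=p, fdr=float(q), direction=d)
        for (pw, a, np_, stat, p, d), q in zip(results, fdr)
    ]
    out.sort(key=lambda r: (r.p, -r.statistic))
    return out


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                pathway=r.pathway,
                focal_count=r.a,
                pathway_size=r.n_path,
                chi2=r.statistic,
                p_value=r.p,
                fdr=r.fdr,
                direction=r.direction,
            )
            for r in results
        ]
    )
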