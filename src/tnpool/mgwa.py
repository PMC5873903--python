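"""Metagenome-wide association of gene-family presence with host load.

Each orthologous group (OG) is tested for association between its
presence/absence pattern across bacterial strains and log-transformed CFU
loads of host animals monoassociated with those strains. The model per OG is

    log(CFU) = intercept + beta * presence + u_experiment + u_strain + eps

with independent zero-mean random effects for experiment and strain
(crossed, encoded as two variance components on a single grouping) and the
presence coefficient tested by a likelihood-ratio test between ML fits of
the nested models. Variance components are constrained non-negative;
boundary fits are reported, not errored. Zero CFU counts are replaced by 1
before logging and flagged.

Bonferroni correction is applied over the number of OGs actually tested;
the "top set" (default raw p < 0.001) feeds the pathway-enrichment step.
The mutant-load comparison uses the same machinery with treatment as a
fixed effect and experiment as the single random effect, contrasting each
treatment against the control with Wald tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec

from .enrichment import (
    DEFAULT_B,
    DEFAULT_MIN_COUNT,
    EnrichmentResult,
    enrichment_scan,
)
from .synth import LoadTable, StrainPanel

__all__ = [
    "MGWAResult",
    "LoadComparison",
    "fit_og_association",
    "run_mgwa",
    "top_hit_enrichment",
    "compare_loads",
]

logger = logging.getLogger(__name__)

TOP_SET_P_CUTOFF = 0.001


@dataclass(frozen=True)
class MGWAResult:
    og: str
    n_present: int
    n_absent: int
    effect: float | None  # presence - absence difference in mean log CFU
    p: float | None
    p_bonferroni: float | None = None
    status: str = "tested"  # tested | monomorphic | failed
    message: str = ""


@dataclass(frozen=True)
class LoadComparison:
    treatment: str
    effect: float  # log-CFU shift vs control
    p: float | None
    significant: bool
    is_control: bool = False


def _log_cfu(counts: pd.Series) -> tuple[np.ndarray, int]:
    """Natural log of CFU counts, zeros replaced by 1 (count returned)."""
    c = counts.to_numpy(dtype=float)
    n_zero = int((c == 0).sum())
    return np.log(np.maximum(c, 1.0)), n_zero


def _crossed_vcspec(phen: pd.DataFrame) -> VCSpec:
    """Experiment and strain as crossed variance components (single group)."""
    exp_codes, exp_levels = pd.factorize(phen["experiment_id"])
    str_codes, str_levels = pd.factorize(phen["strain_id"])
    z_exp = (exp_codes[:, None] == np.arange(len(exp_levels))).astype(float)
    z_str = (str_codes[:, None] == np.arange(len(str_levels))).astype(float)
    return VCSpec(
        names=["experiment", "strain"],
        colnames=[[list(map(str, exp_levels))], [list(map(str, str_levels))]],
        mats=[[z_exp], [z_str]],
    )


def _fit_ml(y: np.ndarray, X: np.ndarray, vcs: VCSpec):
    """ML log-likelihood of a mixed model, or None on failure."""
    groups = np.zeros(len(y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(y, X, groups, exog_vc=vcs).fit(reml=False)
    if not np.isfinite(res.llf):
        return None
    return res


def fit_og_association(panel: StrainPanel, og: str, test: str = "lrt") -> MGWAResult:
    """Mixed-model association test for one orthologous group.

    ``test`` is "lrt" (likelihood-ratio between ML fits, default) or "wald"
    (z-test of the presence coefficient in the full model). OGs with fewer
    than 2 strains in either presence class are returned untested
    (status "monomorphic").
    """
    presence_by_strain = panel.og_presence[og]
    phen = panel.phenotypes
    pres = phen["strain_id"].map(presence_by_strain).to_numpy(dtype=float)
    n_present = int(presence_by_strain.sum())
    n_absent = int(len(presence_by_strain) - n_present)
    if n_present < 2 or n_absent < 2:
        return MGWAResult(
            og=og, n_present=n_present, n_absent=n_absent,
            effect=None, p=None, status="monomorphic",
        )
    y, n_zero = _log_cfu(phen["cfu_count"])
    if n_zero:
        logger.info("OG %s: %d zero CFU counts replaced by 1 before logging", og, n_zero)
    vcs = _crossed_vcspec(phen)
    n = len(y)
    X1 = np.column_stack([np.ones(n), pres])
    try:
        full = _fit_ml(y, X1, vcs)
        if full is None:
            raise ValueError("non-finite likelihood in full model")
        beta = float(full.params[1])
        if test == "wald":
            p = float(full.pvalues[1])
        else:
            null = _fit_ml(y, np.ones((n, 1)), vcs)
            if null is None:
                raise ValueError("non-finite likelihood in null model")
            lr = max(2.0 * (full.llf - null.llf), 0.0)
            p = float(stats.chi2.sf(lr, df=1))
    except (ValueError, np.linalg.LinAlgError) as exc:
        return MGWAResult(
            og=og, n_present=n_present, n_absent=n_absent,
            effect=None, p=None, status="failed", message=str(exc),
        )
    return MGWAResult(
        og=og, n_present=n_present, n_absent=n_absent, effect=beta, p=p,
    )


def run_mgwa(
    panel: StrainPanel,
    cutoff: float = TOP_SET_P_CUTOFF,
    use_corrected_cutoff: bool = False,
    test: str = "lrt",
) -> tuple[list[MGWAResult], list[str]]:
    """Test every polymorphic OG; return results and the top-hit set.

    Bonferroni multiplies each raw p by the number of OGs actually tested
    (capped at 1). The top set collects OGs with raw p below ``cutoff``
    (or Bonferroni-adjusted p, with ``use_corrected_cutoff``).
    """
    results = [fit_og_association(panel, og, test=test) for og in panel.og_ids]
    m = sum(r.status == "tested" for r in results)
    adjusted = []
    for r in results:
        if r.status == "tested":
            adjusted.append(
                MGWAResult(
                    og=r.og, n_present=r.n_present, n_absent=r.n_absent,
                    effect=r.effect, p=r.p,
                    p_bonferroni=min(1.0, r.p * m),
                )
            )
        else:
            adjusted.append(r)
    top = [
        r.og
        for r in adjusted
        if r.status == "tested"
        and (r.p_bonferroni if use_corrected_cutoff else r.p) < cutoff
    ]
    n_failed = sum(r.status == "failed" for r in adjusted)
    if n_failed:
        logger.warning("%d OG fits failed and were excluded from correction", n_failed)
    return adjusted, top


def top_hit_enrichment(
    top_labels: dict[str, set[str]],
    reference_labels: dict[str, set[str]],
    B: int = DEFAULT_B,
    min_count: int | None = DEFAULT_MIN_COUNT,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Pathway enrichment of top association hits against all OGs.

    ``top_labels`` / ``reference_labels`` map OG id -> pathway ids; the top
    set must be a subset of the reference (which includes it). Per pathway
    the 2x2 table contrasts top-set membership inside vs outside the
    pathway. Pathways with fewer than ``min_count`` OGs in either the top
    or the reference set are excluded before testing.
    """
    extra = set(top_labels) - set(reference_labels)
    if extra:
        raise ValueError(f"top OGs absent from reference: {sorted(extra)}")
    pathways = sorted({p for labels in reference_labels.values() for p in labels})
    counts = pd.DataFrame(
        {
            "a": [
                sum(1 for labels in top_labels.values() if p in labels) for p in pathways
            ],
            "n_path": [
                sum(1 for labels in reference_labels.values() if p in labels)
                for p in pathways
            ],
        },
        index=pd.Index(pathways, name="pathway"),
    )
    return enrichment_scan(
        counts,
        focal_total=len(top_labels),
        universe_total=len(reference_labels),
        B=B,
        min_count=min_count,
        min_count_on="both",
        directions=("enriched", "depleted"),
        seed=seed,
    )


def compare_loads(loads: LoadTable, alpha: float = 0.05) -> list[LoadComparison]:
    """Contrast each treatment's log CFU load against the control.

    Fits log(CFU) = intercept + treatment fixed effects + u_experiment + eps
    (random experiment intercept) by ML and reports the Wald p-value of each
    non-control coefficient. With a single experiment the random effect is
    inestimable: an ordinary least-squares fit is used instead, with a loud
    warning.
    """
    df = loads.rows
    control = loads.control_treatment
    y, n_zero = _log_cfu(df["cfu_count"])
    if n_zero:
        logger.info("%d zero CFU counts replaced by 1 before logging", n_zero)
    treatments = [control] + sorted(set(df["treatment_id"]) - {control})
    t_codes = pd.Categorical(df["treatment_id"], categories=treatments).codes
    X = np.column_stack(
        [np.ones(len(df))] + [(t_codes == i).astype(float) for i in range(1, len(treatments))]
    )
    n_experiments = df["experiment_id"].nunique()
    if n_experiments < 2:
        warnings.warn(
            "single experiment: experiment random effect inestimable, "
            "falling back to a fixed-effects (OLS) model",
            stacklevel=2,
        )
        import statsmodels.api as sm

        res = sm.OLS(y, X).fit()
    else:
        groups = pd.factorize(df["experiment_id"])[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, X, groups).fit(reml=False)
    out = [LoadComparison(treatment=control, effect=0.0, p=None, significant=False, is_control=True)]
    for i, t in enumerate(treatments[1:], start=1):
        p = float(res.pvalues[i])
        out.append(
            LoadComparison(
                treatment=t, effect=float(res.params[i]), p=p, significant=p < alpha
            )
        )
    return out


def mgwa_results_to_frame(results: list[MGWAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                og=r.og,
                n_present=r.n_present,
                n_absent=r.n_absent,
                effect=r.effect,
                p_value=r.p,
                p_bonferroni=r.p_bonferroni,
                status=r.status,
            )
            for r in results
        ]
    )
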