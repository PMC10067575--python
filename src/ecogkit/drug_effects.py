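"""Per-subject pre/post drug-effect metrics and cross-subject statistics.

Each subject contributes exactly one pre-drug and one post-drug data
point per metric (the epoch-averaged block values).  The drug effect on
a metric is the change ratio

    ratio = value_post / value_pre,

so 1 means no change and 0.4 a 60% reduction.  Subjects are binned into
responder categories by their spike-rate ratio, category proportions
between drug groups are compared with Fisher's exact test, and the
dependence structure across metrics is summarized by a matrix of
Spearman rank correlations (exact permutation p-values at small n,
t-approximation otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, SizeError
from .spectral import BandPowers
from .spikes import SpikeStats

__all__ = [
    "ResponderBins",
    "BlockMetrics",
    "SubjectSummary",
    "DrugEffect",
    "CorrelationMatrix",
    "summarize_subject",
    "compute_drug_effect",
    "spearman_matrix",
    "category_table_test",
    "fisher_exact_2x2",
    "DEFAULT_METRICS",
]

EXACT_PERMUTATION_MAX_N = 9


@dataclass(frozen=True)
class ResponderBins:
    """Ordered responder categories on the spike-rate change ratio.

    The default bins reconstruct the narrative categories (">50%
    reduction", "20-50%", "10-20%", no change, increase) and partition
    (0, inf); each entry is (name, low, high) with low inclusive, high
    exclusive, except that the final bin is open above.
    """

    categories: tuple[tuple[str, float, float], ...] = (
        ("reduction >50%", 0.0, 0.5),
        ("reduction 20-50%", 0.5, 0.8),
        ("reduction 10-20%", 0.8, 0.9),
        ("no change/small", 0.9, 1.1 + 1e-12),  # 0.9 <= r <= 1.1 inclusive
        ("increase", 1.1 + 1e-12, math.inf),
    )

    def __post_init__(self):
        lo = 0.0
        for name, a, b in self.categories:
            if not math.isclose(a, lo, abs_tol=1e-9):
                raise ValueError(f"responder bins must partition (0, inf); gap before {name!r}")
            if b <= a:
                raise ValueError(f"bin {name!r} has nonpositive width")
            lo = b
        if not math.isinf(lo):
            raise ValueError("final responder bin must be open above")

    def categorize(self, ratio: float) -> str:
        if not (ratio > 0 and math.isfinite(ratio)):
            raise DegenerateInputError(f"change ratio {ratio} outside (0, inf)")
        for name, a, b in self.categories:
            if a <= ratio < b:
                return name
        return self.categories[-1][0]

    def is_reduction(self, category: str) -> bool:
        return category.startswith("reduction")


@dataclass
class BlockMetrics:
    """Everything the pipeline measures on one analysis block."""

    band_powers: BandPowers
    coherence_band_means: dict[str, float]
    spike_stats: SpikeStats
    qc_pass: bool = True

    @property
    def theta_beta_ratio(self) -> float:
        beta = self.band_powers.relative["beta"]
        if beta <= 0:
            return math.nan
        return self.band_powers.relative["theta"] / beta

    @property
    def theta_beta_gamma_ratio(self) -> float:
        denom = self.band_powers.relative["beta"] + self.band_powers.relative["gamma"]
        if denom <= 0:
            return math.nan
        return self.band_powers.relative["theta"] / denom


@dataclass
class SubjectSummary:
    """One row per subject: pre and post block metrics plus derived ratios."""

    subject_id: str
    pre: BlockMetrics
    post: BlockMetrics
    drug: str = ""
    excluded: bool = False
    exclusion_reason: str = ""

    def metric_values(self, block: str) -> dict[str, float]:
        m: BlockMetrics = getattr(self, block)
        out = {"spike_rate": m.spike_stats.rate_per_min,
               "total_power": m.band_powers.total}
        for band, pct in m.band_powers.relative.items():
            out[f"rel_{band}"] = pct
        for band, coh in m.coherence_band_means.items():
            out[f"coh_{band}"] = coh
        out["theta_beta_ratio"] = m.theta_beta_ratio
        out["theta_beta_gamma_ratio"] = m.theta_beta_gamma_ratio
        return out


@dataclass
class DrugEffect:
    """Post/pre change ratios for one subject plus its responder category."""

    subject_id: str
    drug: str
    ratios: dict[str, float]          # metric -> post/pre; NaN when undefined
    undefined: set[str]
    responder_category: str | None

    def to_dict(self) -> dict:
        d = {"subject_id": self.subject_id, "drug": self.drug,
             "responder_category": self.responder_category}
        d.update({f"ratio_{k}": v for k, v in self.ratios.items()})
        return d


DEFAULT_METRICS = (
    "spike_rate", "total_power",
    "rel_delta", "rel_theta", "rel_alpha", "rel_beta", "rel_gamma",
    "coh_delta", "coh_theta", "coh_alpha", "coh_beta", "coh_gamma",
    "theta_beta_ratio", "theta_beta_gamma_ratio",
)


def summarize_subject(subject_id: str, pre: BlockMetrics, post: BlockMetrics,
                      drug: str = "") -> SubjectSummary:
    """Combine both blocks into a subject row; QC failure flags exclusion."""
    summary = SubjectSummary(subject_id=subject_id, pre=pre, post=post, drug=drug)
    if not (pre.qc_pass and post.qc_pass):
        summary.excluded = True
        failing = [lbl for lbl, m in (("pre", pre), ("post", post)) if not m.qc_pass]
        summary.exclusion_reason = f"epoch QC failed in block(s): {', '.join(failing)}"
    return summary


def compute_drug_effect(summary: SubjectSummary,
                        bins: ResponderBins | None = None) -> DrugEffect:
    """All post/pre change ratios for one subject.

    A metric with a nonpositive or undefined pre value yields NaN for that
    ratio (and is listed in ``undefined``) without affecting the others.
    The responder category comes from the spike-rate ratio.
    """
    bins = bins or ResponderBins()
    pre_vals = summary.metric_values("pre")
    post_vals = summary.metric_values("post")
    ratios: dict[str, float] = {}
    undefined: set[str] = set()
    for name, pre_v in pre_vals.items():
        post_v = post_vals[name]
        if not (pre_v > 0 and math.isfinite(pre_v) and math.isfinite(post_v)):
            ratios[name] = math.nan
            undefined.add(name)
        else:
            ratios[name] = post_v / pre_v
    spike_ratio = ratios.get("spike_rate", math.nan)
    category = None
    if math.isfinite(spike_ratio) and spike_ratio > 0:
        category = bins.categorize(spike_ratio)
    return DrugEffect(subject_id=summary.subject_id, drug=summary.drug,
                      ratios=ratios, undefined=undefined,
                      responder_category=category)


def effects_to_frame(effects: list[DrugEffect]) -> pd.DataFrame:
    return pd.DataFrame([e.to_dict() for e in effects])


# ---------------------------------------------------------------------------
# Spearman correlation matrix

@dataclass
class CorrelationMatrix:
    """Pairwise Spearman rho, two-sided p, and per-pair n over subjects."""

    metrics: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a, b in itertools.combinations_with_replacement(self.metrics, 2):
            rows.append({"metric_a": a, "metric_b": b,
                         "rho": self.rho.loc[a, b],
                         "p": self.p.loc[a, b],
                         "n": self.n.loc[a, b]})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "metrics": list(self.metrics),
            "rho": self.rho.to_numpy().tolist(),
            "p": self.p.to_numpy().tolist(),
            "n": self.n.to_numpy().tolist(),
        }


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho at small n.

    Enumerates all n! orderings of one variable's ranks; ties are handled
    by average ranks (the permutation distribution conditions on the
    observed tie pattern).
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    if denom == 0:
        return 1.0
    r_obs = float(rx_c @ ry_c) / denom
    perms = np.array(list(itertools.permutations(ry_c)))
    r_all = perms @ rx_c / denom
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


def spearman_pair(x, y, exact_max_n: int = EXACT_PERMUTATION_MAX_N) -> tuple[float, float, int]:
    """(rho, two-sided p, n) for one metric pair on complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = int(ok.sum())
    if n < 3:
        return math.nan, math.nan, n
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if n <= exact_max_n:
        p = _spearman_exact_p(x, y)
    else:
        p = float(res.pvalue)
    return rho, p, n


def spearman_matrix(effects: list[DrugEffect],
                    metrics: tuple[str, ...] = DEFAULT_METRICS,
                    exact_max_n: int = EXACT_PERMUTATION_MAX_N) -> CorrelationMatrix:
    """Cross-subject Spearman surface over the change ratios.

    Uses pairwise-complete observations; pairs with fewer than 3 complete
    subjects are flagged not-computable (NaN rho and p).
    """
    if len(effects) < 3:
        raise SizeError("spearman_matrix needs at least 3 subjects")
    df = pd.DataFrame([{m: e.ratios.get(m, math.nan) for m in metrics} for e in effects])
    k = len(metrics)
    rho = np.eye(k)
    pval = np.full((k, k), math.nan)
    nmat = np.zeros((k, k), dtype=int)
    for i in range(k):
        nmat[i, i] = int(np.isfinite(df[metrics[i]]).sum())
        pval[i, i] = 0.0
        for j in range(i + 1, k):
            r, p, n = spearman_pair(df[metrics[i]], df[metrics[j]], exact_max_n)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
            nmat[i, j] = nmat[j, i] = n
    idx = list(metrics)
    return CorrelationMatrix(
        metrics=tuple(metrics),
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(pval, index=idx, columns=idx),
        n=pd.DataFrame(nmat, index=idx, columns=idx),
    )


# ---------------------------------------------------------------------------
# category-proportion test

def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 contingency table."""
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def category_table_test(group_a: list[str], group_b: list[str],
                        bins: ResponderBins | None = None) -> float:
    """Fisher exact test on responder-category proportions of two groups.

    Categories are collapsed to a 2x2 table (reduction vs non-reduction by
    the default bins) before testing.
    """
    bins = bins or ResponderBins()
    if not group_a or not group_b:
        raise SizeError("category_table_test needs two nonempty groups")
    a_dec = sum(bins.is_reduction(c) for c in group_a)
    b_dec = sum(bins.is_reduction(c) for c in group_b)
    table = [[a_dec, len(group_a) - a_dec],
             [b_dec, len(group_b) - b_dec]]
    return fisher_exact_2x2(table)
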