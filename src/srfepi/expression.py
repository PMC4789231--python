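"""Differential-expression cascade for a 2x2 genotype x treatment design.

The analysis mirrors a microarray workflow on hippocampal dentate gyrus
expression after kainic-acid (KA) induced status epilepticus in control (CTR)
versus conditional SRF-knockout (KO) mice: quantile normalization, log2
transform, per-probe two-way ANOVA with a genotype x treatment interaction
screen (raw p and Benjamini-Hochberg FDR), Tukey HSD pairwise contrasts, and
nested fold-change tiers:

* KA-responsive: |fold| beyond 1.5 / 0.66 in CTR with Tukey p < 0.05;
* genotype-differential: CTR-KA vs KO-KA fold beyond 1.5 / 0.66, Tukey p < 0.05;
* SRF-dependent (up/down): interaction p < 0.0005 and FDR < 1 % plus the CTR
  fold filter;
* heatmap tiers: the strongest SRF-dependent changes (CTR fold > 2.5 with
  KO/CTR fold < 0.51, or CTR fold < 0.4 with KO/CTR fold > 1.96).

All thresholds are strict inequalities and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from ._stats import studentized_range_sf

GENOTYPES = ("CTR", "KO")
TREATMENTS = ("saline", "KA")
#: design cells in fixed order: (genotype, treatment)
CELLS = tuple((g, t) for g in GENOTYPES for t in TREATMENTS)

_ZERO_SS = 1e-12


@dataclass
class ExpressionMatrix:
    """Probe x sample intensity matrix with an explicit scale tag."""

    values: pd.DataFrame  # rows = probes, columns = samples
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in {"linear", "log2"}:
            raise ValueError(f"scale must be 'linear' or 'log2', got {self.scale!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.scale == "linear" and (self.values.to_numpy() <= 0).any():
            raise ValueError("linear-scale intensities must be positive")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def validate_sample_sheet(sheet: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    required = {"sample_id", "genotype", "treatment"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    bad_g = set(sheet["genotype"]) - set(GENOTYPES)
    bad_t = set(sheet["treatment"]) - set(TREATMENTS)
    if bad_g or bad_t:
        raise ValueError(f"unknown genotype/treatment labels: {bad_g | bad_t}")
    for g, t in CELLS:
        if ((sheet["genotype"] == g) & (sheet["treatment"] == t)).sum() == 0:
            raise ValueError(f"design cell {g}/{t} is empty")
    if matrix is not None:
        if set(sheet["sample_id"]) != set(matrix.sample_ids):
            raise ValueError("sample sheet ids do not match matrix columns")
    return sheet


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to the common distribution of column-sorted row means.

    Each column is replaced by the mean sorted vector, assigned back in the
    column's own rank order (ties broken by position), so the sorted vector of
    every output column is identical.
    """
    if m.scale != "linear":
        raise ValueError("quantile normalization expects linear-scale intensities")
    if m.values.shape[1] < 2:
        raise ValueError("need more than one sample")
    x = m.values.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[order[:, j], j] = target
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        scale="linear",
    )


def log2_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    if m.scale != "linear":
        raise ValueError("matrix is already log2-scaled")
    return ExpressionMatrix(np.log2(m.values), scale="log2")


def bh_fdr(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values, proportions)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def _cell_masks(sheet: pd.DataFrame, sample_ids: pd.Index) -> dict[tuple[str, str], np.ndarray]:
    s = sheet.set_index("sample_id").loc[sample_ids]
    return {
        (g, t): ((s["genotype"] == g) & (s["treatment"] == t)).to_numpy()
        for g, t in CELLS
    }


def _rss(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each row of y regressed on `design`."""
    q, _ = np.linalg.qr(design)
    proj = y @ q
    rss = (y * y).sum(axis=1) - (proj * proj).sum(axis=1)
    return np.clip(rss, 0.0, None)


def fit_two_way_anova(m: ExpressionMatrix, sheet: pd.DataFrame) -> pd.DataFrame:
    """Per-probe 2x2 ANOVA, Tukey-Kramer contrasts, FDR and fold changes.

    Returns a probe-indexed frame (ProbeStats): cell means on the log2 scale,
    Type II F/p for both main effects, the interaction F/p/q (the interaction
    test is identical under Type II/III in a 2x2), Tukey HSD p-values for the
    CTR-KA vs CTR-saline, CTR-KA vs KO-KA and KO-KA vs KO-saline contrasts
    using the pooled within-cell error (Tukey-Kramer for unequal n), and
    linear fold changes from differences of mean log2 (geometric means).

    Probes with zero within-cell variance are flagged ``degenerate``; their
    test p-values are 0 where the effect sum of squares is nonzero and 1 where
    it is exactly zero.
    """
    if m.scale != "log2":
        raise ValueError("ANOVA expects a log2-scale matrix")
    validate_sample_sheet(sheet, m)
    masks = _cell_masks(sheet, m.sample_ids)
    ns = {cell: int(mask.sum()) for cell, mask in masks.items()}
    if min(ns.values()) < 2:
        raise ValueError("need >= 2 samples in every design cell")

    y = m.values.to_numpy(dtype=float)
    n = y.shape[1]
    dfe = n - 4

    a = masks[("KO", "saline")] | masks[("KO", "KA")]
    b = masks[("CTR", "KA")] | masks[("KO", "KA")]
    one = np.ones(n)
    x_full = np.column_stack([one, a, b, a & b]).astype(float)
    x_add = x_full[:, :3]
    x_a = x_full[:, :2]
    x_b = np.column_stack([one, b.astype(float)])

    rss_full = _rss(y, x_full)
    rss_add = _rss(y, x_add)
    rss_a = _rss(y, x_a)
    rss_b = _rss(y, x_b)

    ss_int = np.clip(rss_add - rss_full, 0.0, None)
    ss_geno = np.clip(rss_b - rss_add, 0.0, None)  # Type II: SS(A | B)
    ss_treat = np.clip(rss_a - rss_add, 0.0, None)
    mse = rss_full / dfe
    degenerate = mse <= _ZERO_SS

    def f_and_p(ss: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(degenerate, np.where(ss > _ZERO_SS, np.inf, 0.0), ss / mse)
        p = np.where(degenerate, np.where(ss > _ZERO_SS, 0.0, 1.0), f_dist.sf(np.where(degenerate, 0.0, f), 1, dfe))
        return f, p

    f_int, p_int = f_and_p(ss_int)
    f_geno, p_geno = f_and_p(ss_geno)
    f_treat, p_treat = f_and_p(ss_treat)
    q_int = bh_fdr(p_int)

    means = {cell: y[:, mask].mean(axis=1) for cell, mask in masks.items()}

    contrasts = {
        "p_tukey_ctrka_ctrsal": (("CTR", "KA"), ("CTR", "saline")),
        "p_tukey_ctrka_koka": (("CTR", "KA"), ("KO", "KA")),
        "p_tukey_koka_kosal": (("KO", "KA"), ("KO", "saline")),
    }
    tukey: dict[str, np.ndarray] = {}
    for name, (c1, c2) in contrasts.items():
        diff = np.abs(means[c1] - means[c2])
        se = np.sqrt(mse / 2.0 * (1.0 / ns[c1] + 1.0 / ns[c2]))
        with np.errstate(divide="ignore", invalid="ignore"):
            qstat = np.where(degenerate, np.where(diff > 0, np.inf, 0.0), diff / se)
        p = np.where(
            degenerate,
            np.where(diff > 0, 0.0, 1.0),
            studentized_range_sf(np.where(np.isfinite(qstat), qstat, 0.0), 4, dfe),
        )
        tukey[name] = p

    fc_ctr = 2.0 ** (means[("CTR", "KA")] - means[("CTR", "saline")])
    fc_geno = 2.0 ** (means[("KO", "KA")] - means[("CTR", "KA")])
    fc_ko = 2.0 ** (means[("KO", "KA")] - means[("KO", "saline")])

    return pd.DataFrame(
        {
            "mean_ctr_saline": means[("CTR", "saline")],
            "mean_ctr_ka": means[("CTR", "KA")],
            "mean_ko_saline": means[("KO", "saline")],
            "mean_ko_ka": means[("KO", "KA")],
            "F_genotype": f_geno,
            "p_genotype": p_geno,
            "F_treatment": f_treat,
            "p_treatment": p_treat,
            "F_interaction": f_int,
            "p_interaction": p_int,
            "q_interaction": q_int,
            **tukey,
            "fc_ctr": fc_ctr,
            "fc_geno": fc_geno,
            "fc_ko": fc_ko,
            "degenerate": degenerate,
        },
        index=m.probe_ids,
    )


@dataclass(frozen=True)
class ClassificationThresholds:
    """Strict cutoffs for the nested tiers (defaults as used in the study)."""

    fc_up: float = 1.5
    fc_down: float = 0.66
    tukey_alpha: float = 0.05
    p_interaction: float = 0.0005
    fdr: float = 0.01  # proportion, i.e. FDR < 1 %
    heat_up_fc: float = 2.5
    heat_up_geno: float = 0.51  # KO-KA / CTR-KA fold below this
    heat_down_fc: float = 0.4
    heat_down_geno: float = 1.96


@dataclass
class ClassificationResult:
    probes: pd.DataFrame  # probe-level flags, with gene_id (may be NaN)
    genes: pd.DataFrame  # gene-level flags (any probe flagged)


TIER_COLUMNS = (
    "ka_responsive",
    "genotype_differential",
    "srf_dependent_up",
    "srf_dependent_down",
    "heatmap_up",
    "heatmap_down",
)


def classify(
    stats: pd.DataFrame,
    probe_gene_map: Mapping[str, str] | pd.Series | None = None,
    thresholds: ClassificationThresholds | None = None,
) -> ClassificationResult:
    """Apply the nested tier filters to per-probe statistics.

    A gene is flagged for a tier if any of its probes is flagged.  Probes
    without a gene mapping are retained with ``gene_id`` NaN and marked
    ``unmapped``; they do not contribute to gene-level flags.
    """
    th = thresholds or ClassificationThresholds()
    fc_ctr = stats["fc_ctr"]
    fc_geno = stats["fc_geno"]
    fc_ctrka_vs_koka = 1.0 / fc_geno

    ka_resp = ((fc_ctr > th.fc_up) | (fc_ctr < th.fc_down)) & (
        stats["p_tukey_ctrka_ctrsal"] < th.tukey_alpha
    )
    geno_diff = (
        (fc_ctrka_vs_koka > th.fc_up) | (fc_ctrka_vs_koka < th.fc_down)
    ) & (stats["p_tukey_ctrka_koka"] < th.tukey_alpha)
    interaction_ok = (stats["p_interaction"] < th.p_interaction) & (
        stats["q_interaction"] < th.fdr
    )
    srf_up = interaction_ok & (fc_ctr > th.fc_up)
    srf_down = interaction_ok & (fc_ctr < th.fc_down)
    heat_up = srf_up & (fc_ctr > th.heat_up_fc) & (fc_geno < th.heat_up_geno)
    heat_down = srf_down & (fc_ctr < th.heat_down_fc) & (fc_geno > th.heat_down_geno)

    probes = pd.DataFrame(
        {
            "ka_responsive": ka_resp,
            "genotype_differential": geno_diff,
            "srf_dependent_up": srf_up,
            "srf_dependent_down": srf_down,
            "heatmap_up": heat_up,
            "heatmap_down": heat_down,
        },
        index=stats.index,
    )
    if probe_gene_map is None:
        probes.insert(0, "gene_id", pd.Series(stats.index, index=stats.index))
    else:
        mapping = pd.Series(probe_gene_map) if not isinstance(probe_gene_map, pd.Series) else probe_gene_map
        probes.insert(0, "gene_id", mapping.reindex(stats.index))
    probes["unmapped"] = probes["gene_id"].isna()

    mapped = probes[~probes["unmapped"]]
    genes = mapped.groupby("gene_id")[list(TIER_COLUMNS)].any()
    genes.index.name = "gene_id"
    return ClassificationResult(probes=probes, genes=genes)


def tier_report(c: ClassificationResult) -> dict:
    """Counts per tier (probes and genes) plus the KA-responsive remainder.

    The remainder is the set of KA-responsive probes that are not also
    genotype-differential, reported as a count and a percentage of the
    KA-responsive pool (one decimal); the percentage is None when no probe is
    KA-responsive.
    """
    p, g = c.probes, c.genes
    n_ka = int(p["ka_responsive"].sum())
    n_both = int((p["ka_responsive"] & p["genotype_differential"]).sum())
    remainder = n_ka - n_both
    report = {
        "probes": {t: int(p[t].sum()) for t in TIER_COLUMNS},
        "genes": {t: int(g[t].sum()) for t in TIER_COLUMNS},
        "srf_dependent_probes": int((p["srf_dependent_up"] | p["srf_dependent_down"]).sum()),
        "srf_dependent_genes": int((g["srf_dependent_up"] | g["srf_dependent_down"]).sum()),
        "remainder_count": remainder,
        "remainder_pct": round(100.0 * remainder / n_ka, 1) if n_ka else None,
    }
    return report


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------


def read_matrix_tsv(path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, scale=scale)


def write_matrix_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return validate_sample_sheet(pd.read_csv(path, sep="\t"))
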