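"""Direction-stratified Venn classification of interaction-responsive genes.

The experimental design crosses Spiroplasma infection (S+/S-) with
parasitoid-wasp exposure (no wasp / wasp) and asks which host genes respond
specifically to the *interaction* of symbiont and wasp. Three pairwise
contrasts carry the signal:

* blue  — S-W- vs S+W- : effect of Spiroplasma in the absence of wasps
* red   — S-W- vs S-wasp : effect of the wasp in the absence of Spiroplasma
* green — S-wasp vs S+wasp : effect of Spiroplasma in parasitized hosts

Differentially expressed genes from the three contrasts are laid out in a
Venn diagram, **separately for up- and down-regulated sets** — a gene can be,
say, exclusively down in green and simultaneously exclusively up in red.
That double-exclusive pattern defines the "restored" genes: wasp parasitism
shifts their expression away from the control and co-infection with
Spiroplasma brings it back.

* Group A — exclusively down in green AND exclusively up in red
  (wasp raises expression; Spiroplasma restores it)
* Group B — exclusively up in green AND exclusively down in red
  (wasp lowers expression; Spiroplasma restores it); up-regulated
  blue∩green genes matching the restored expression shape are annotated
  "B-like" rather than merged
* Group C — up in green (exclusive or shared with red) with the highest
  expression in the S+wasp treatment while the other three treatments sit
  at similar levels
* male-gonad pattern — S-W- > S-wasp > S+W- = S+wasp in treatment-mean
  z-scores: male-biased transcripts depleted by the male-killing symbiont
  and partially reduced by wasp parasitism

Group calls operate on treatment means of per-gene z-scores of
TMM-normalized expression, with explicit separation (delta, z-units) and
similarity (epsilon) thresholds in place of by-eye heatmap clustering.

The differential-expression stage is pluggable: external DE tables are
first-class input, and a built-in negative-binomial likelihood-ratio test
with a single moment-matched common dispersion exists so the pipeline is
testable end-to-end without external software.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .io_formats import ConfigurationError, RunConfig

CONTRAST_NAMES = ("blue", "red", "green")
REGIONS = (
    "blue_only", "red_only", "green_only",
    "blue_red", "blue_green", "red_green", "blue_red_green",
)

TREATMENT_CONTROL = "S-W-"        # Spiroplasma-free, wasp-free
TREATMENT_SPIROPLASMA = "S+W-"    # Spiroplasma only
TREATMENT_WASP = "S-wasp"         # wasp only
TREATMENT_BOTH = "S+wasp"         # Spiroplasma + wasp


class DataError(ValueError):
    """Inconsistent data passed to a set-logic or normalization step."""


@dataclass(frozen=True)
class DEGene:
    gene_id: str
    log2fc: float
    fdr: float

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else "down"


@dataclass
class DEComparison:
    """One named contrast (blue/red/green) with per-gene DE results."""

    name: str
    genes: list[DEGene]

    def __post_init__(self) -> None:
        if self.name not in CONTRAST_NAMES:
            raise ValueError(f"contrast name must be one of {CONTRAST_NAMES}")
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise DataError(f"duplicate gene ids in contrast {self.name!r}")


@dataclass
class VennPartition:
    """Disjoint membership regions per direction over the three contrasts."""

    regions: dict = field(default_factory=dict)  # direction -> {gene: region}

    def region_counts(self) -> pd.DataFrame:
        rows = []
        for direction in ("up", "down"):
            counts = {r: 0 for r in REGIONS}
            for region in self.regions.get(direction, {}).values():
                counts[region] += 1
            rows.append({"direction": direction, **counts})
        return pd.DataFrame(rows)

    def genes_in(self, direction: str, region: str) -> set:
        return {g for g, r in self.regions.get(direction, {}).items() if r == region}


@dataclass(frozen=True)
class GroupAssignment:
    gene_id: str
    group: str  # {"A","B","C","male_gonad_pattern","unclassified"}
    evidence: str = ""


# ---------------------------------------------------------------------------
# Design handling
# ---------------------------------------------------------------------------

def treatment_label(spiroplasma: str, wasp: str) -> str:
    s = "S+" if spiroplasma == "present" else "S-"
    return s + ("W-" if wasp == "none" else "wasp")


def design_treatments(design: pd.DataFrame) -> pd.Series:
    """Collapse a design table to the four treatment labels used by the
    pattern classifiers (any wasp species maps to 'wasp')."""
    required = {"sample_id", "spiroplasma", "wasp"}
    if not required.issubset(design.columns):
        raise ConfigurationError(f"design table needs columns {sorted(required)}")
    labels = design.apply(
        lambda r: treatment_label(r["spiroplasma"], r["wasp"]), axis=1
    )
    labels.index = design["sample_id"].values
    return labels


def standard_contrasts(design: pd.DataFrame, wasp: str = "lh") -> dict:
    """Sample-id pairs for the blue/red/green contrasts of one wasp species.

    Each value is (reference samples, treatment samples); fold-changes are
    treatment over reference.
    """
    def sel(spiro, wsp):
        rows = design[(design.spiroplasma == spiro) & (design.wasp == wsp)]
        return list(rows.sample_id)

    contrasts = {
        "blue": (sel("absent", "none"), sel("present", "none")),
        "red": (sel("absent", "none"), sel("absent", wasp)),
        "green": (sel("absent", wasp), sel("present", wasp)),
    }
    for name, (a, b) in contrasts.items():
        if not a or not b:
            raise ConfigurationError(f"contrast {name!r}: empty treatment side")
    return contrasts


# ---------------------------------------------------------------------------
# CPM filtering and TMM normalization
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame, lib_sizes: Optional[pd.Series] = None) -> pd.DataFrame:
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    if (lib_sizes <= 0).any():
        raise DataError("zero or negative library size")
    return counts.div(lib_sizes, axis=1) * 1e6


def cpm_filter(counts: pd.DataFrame, samples_in_pair: Sequence[str]) -> pd.Index:
    """Genes retained for a pairwise comparison: CPM >= 1 in at least one
    replicate of the pair (genes below 1 CPM in every replicate are
    discarded)."""
    sub = counts[list(samples_in_pair)]
    keep = (cpm(sub) >= 1.0).any(axis=1)
    return counts.index[keep]


def _tmm_pairwise_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed mean of M-values of one sample against the reference.

    Doubly trimmed (30% of M-values, 5% of A-values per tail), with inverse
    asymptotic-variance weighting, following the published algorithm.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        logR = np.log2(p_obs / p_ref)
        absE = (np.log2(p_obs) + np.log2(p_ref)) / 2.0
        v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    finite = np.isfinite(logR) & np.isfinite(absE) & (absE > -1e10)
    logR, absE, v = logR[finite], absE[finite], v[finite]
    if logR.size == 0 or np.max(np.abs(logR)) < 1e-6:
        return 1.0
    n = logR.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(logR)
    rank_e = rankdata(absE)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not np.any(keep):
        return 1.0
    f = np.nansum(logR[keep] / v[keep]) / np.nansum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame, reference_sample: Optional[str] = None
) -> pd.Series:
    """Per-sample TMM normalization factors, scaled to geometric mean 1.

    The reference sample, when not given, is the one whose 75th percentile
    of library-scaled counts is closest to the mean across samples.
    """
    if counts.shape[1] < 2:
        raise DataError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise DataError("all-zero sample in count matrix")
    scaled = counts.div(lib, axis=1)
    if reference_sample is None:
        f75 = scaled.quantile(0.75, axis=0)
        reference_sample = f75.index[int(np.argmin(np.abs(f75 - f75.mean())))]
    ref = counts[reference_sample].to_numpy(dtype=float)
    lib_ref = float(lib[reference_sample])
    factors = {}
    for sample in counts.columns:
        if sample == reference_sample:
            factors[sample] = 1.0
        else:
            factors[sample] = _tmm_pairwise_factor(
                counts[sample].to_numpy(dtype=float), ref, float(lib[sample]), lib_ref
            )
    f = pd.Series(factors)[counts.columns]
    return f / np.exp(np.mean(np.log(f)))


def tmm_cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """CPM on TMM effective library sizes (library size x factor)."""
    factors = tmm_factors(counts)
    eff = counts.sum(axis=0) * factors
    return counts.div(eff, axis=1) * 1e6


# ---------------------------------------------------------------------------
# Built-in NB likelihood-ratio DE (test plumbing; external tables first-class)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Row-wise NB log-likelihood, mean mu, dispersion phi (var = mu+phi mu^2)."""
    if phi < 1e-8:
        return np.sum(y * np.log(mu) - mu - gammaln(y + 1.0), axis=-1)
    r = 1.0 / phi
    return np.sum(
        gammaln(y + r) - gammaln(r) - gammaln(y + 1.0)
        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu)),
        axis=-1,
    )


def _nb_fit_mean(y: np.ndarray, elib: np.ndarray, phi: float, n_iter: int = 60) -> np.ndarray:
    """MLE of a per-gene relative abundance q with means mu_gj = q_g * elib_j,
    NB dispersion phi known. Newton on beta = ln q, vectorized over genes."""
    tot = y.sum(axis=1)
    q0 = np.maximum(tot, 0.5) / elib.sum()
    beta = np.log(q0)
    for _ in range(n_iter):
        mu = np.exp(beta)[:, None] * elib[None, :]
        denom = 1.0 + phi * mu
        score = np.sum((y - mu) / denom, axis=1)
        info = np.sum(mu / denom, axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -5, 5)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def estimate_common_dispersion(
    counts: pd.DataFrame, group_samples: Sequence[Sequence[str]]
) -> float:
    """Common NB dispersion (BCV^2) by the pooled Pearson moment equation.

    With per-group fitted means mu (group relative abundance x TMM
    effective library size), the dispersion solves

        sum_gj (y_gj - mu_gj)^2 / (mu_gj + phi mu_gj^2)  =  residual df,

    pooled over all filtered genes; the left side is monotone decreasing in
    phi, so bisection suffices. Unlike a per-gene moment median, this
    pooled estimating equation is close to unbiased for few replicates.
    """
    factors = tmm_factors(counts)
    eff = (counts.sum(axis=0) * factors).to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float)
    cols = list(counts.columns)
    mu = np.zeros_like(y)
    resid_df = 0
    n_groups_used = 0
    for samples in group_samples:
        idx = [cols.index(s) for s in samples]
        if len(idx) < 2:
            continue
        n_groups_used += 1
        q = y[:, idx].sum(axis=1) / eff[idx].sum()
        mu[:, idx] = q[:, None] * eff[None, idx]
        resid_df += len(idx) - 1
    if n_groups_used == 0:
        raise DataError("need >=2 replicates in at least one group")
    used = np.concatenate(
        [[cols.index(s) for s in samples] for samples in group_samples
         if len(samples) >= 2]
    )
    keep = mu[:, used].sum(axis=1) > 0
    yk, muk = y[np.ix_(keep, used)], mu[np.ix_(keep, used)]
    target = float(resid_df * keep.sum())

    def pearson(phi: float) -> float:
        var = muk + phi * muk ** 2
        var = np.where(var > 0, var, 1.0)
        return float(np.sum((yk - muk) ** 2 / var))

    if pearson(0.0) <= target:  # under- or equi-dispersed: Poisson floor
        return 0.0
    lo, hi = 0.0, 10.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if pearson(mid) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10:
            break
    return float((lo + hi) / 2.0)


def reference_de(
    counts: pd.DataFrame,
    contrast: tuple[Sequence[str], Sequence[str]],
    name: str,
    dispersion: Optional[float] = None,
    allow_no_replication: bool = False,
) -> DEComparison:
    """Per-gene NB likelihood-ratio test between the two contrast sides.

    Genes below 1 CPM in every replicate of the pair are removed first;
    library sizes are TMM-corrected; a single common dispersion (supplied
    or moment-matched from the data) is shared by all genes; p-values are
    Benjamini-Hochberg adjusted. Fold-changes are side B over side A with
    a 0.5-count shrinkage to keep them finite at zero counts.
    """
    side_a, side_b = [list(s) for s in contrast]
    if (len(side_a) < 2 or len(side_b) < 2) and not allow_no_replication:
        raise DataError(
            "a contrast side has <2 replicates; pass allow_no_replication=True "
            "to force (dispersion cannot be estimated from the data)"
        )
    pair = side_a + side_b
    kept = cpm_filter(counts, pair)
    sub = counts.loc[kept, pair]
    factors = tmm_factors(sub)
    eff = (sub.sum(axis=0) * factors).to_numpy(dtype=float)
    if dispersion is None:
        dispersion = estimate_common_dispersion(sub, [side_a, side_b])
    y = sub.to_numpy(dtype=float)
    na = len(side_a)
    ya, yb = y[:, :na], y[:, na:]
    ea, eb = eff[:na], eff[na:]

    beta_a = _nb_fit_mean(ya, ea, dispersion)
    beta_b = _nb_fit_mean(yb, eb, dispersion)
    beta_0 = _nb_fit_mean(y, eff, dispersion)

    mu_a = np.exp(beta_a)[:, None] * ea[None, :]
    mu_b = np.exp(beta_b)[:, None] * eb[None, :]
    mu_0 = np.exp(beta_0)[:, None] * eff[None, :]
    ll_full = _nb_loglik(ya, mu_a, dispersion) + _nb_loglik(yb, mu_b, dispersion)
    ll_null = _nb_loglik(y, mu_0, dispersion)
    lrt = np.maximum(0.0, 2.0 * (ll_full - ll_null))
    pvals = stats.chi2.sf(lrt, df=1)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    # shrunk fold-change: 0.5 pseudo-reads on each side's pooled counts
    qa = (ya.sum(axis=1) + 0.5) / ea.sum()
    qb = (yb.sum(axis=1) + 0.5) / eb.sum()
    log2fc = np.log2(qb / qa)

    genes = [
        DEGene(gene_id=str(g), log2fc=float(l), fdr=float(f))
        for g, l, f in zip(sub.index, log2fc, fdr)
    ]
    return DEComparison(name=name, genes=genes)


# ---------------------------------------------------------------------------
# DE thresholding and Venn set logic
# ---------------------------------------------------------------------------

def de_filter(
    comparison: DEComparison, lfc_min: float = 0.58, fdr_max: float = 0.05
) -> dict:
    """DE calls at |log2FC| >= lfc_min and FDR < fdr_max, split by direction."""
    up = {g.gene_id for g in comparison.genes
          if g.fdr < fdr_max and g.log2fc >= lfc_min}
    down = {g.gene_id for g in comparison.genes
            if g.fdr < fdr_max and g.log2fc <= -lfc_min}
    return {"up": up, "down": down}


def _region_of(in_blue: bool, in_red: bool, in_green: bool) -> Optional[str]:
    key = {
        (True, False, False): "blue_only",
        (False, True, False): "red_only",
        (False, False, True): "green_only",
        (True, True, False): "blue_red",
        (True, False, True): "blue_green",
        (False, True, True): "red_green",
        (True, True, True): "blue_red_green",
    }
    return key.get((in_blue, in_red, in_green))


def venn_partition(
    blue: DEComparison,
    red: DEComparison,
    green: DEComparison,
    config: RunConfig = RunConfig(),
) -> VennPartition:
    """Direction-stratified Venn regions over the three contrasts.

    Up- and down-regulated gene sets get separate partitions; within each
    direction the seven regions are disjoint and cover every DE gene of
    that direction.
    """
    sets = {c.name: de_filter(c, config.lfc_min, config.fdr_max)
            for c in (blue, red, green)}
    partition = VennPartition(regions={"up": {}, "down": {}})
    for direction in ("up", "down"):
        b, r, g = (sets[n][direction] for n in CONTRAST_NAMES)
        for gene in b | r | g:
            region = _region_of(gene in b, gene in r, gene in g)
            partition.regions[direction][gene] = region
    return partition


# ---------------------------------------------------------------------------
# Expression-pattern classifiers
# ---------------------------------------------------------------------------

def zscore_treatment_means(
    expr: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Treatment means of per-gene z-scores (z across all samples).

    Returns genes x four treatment labels. Genes with zero variance get
    z = 0 everywhere (they can never clear a separation threshold, so
    ties break toward 'unclassified').
    """
    labels = design_treatments(design)
    missing = [s for s in expr.columns if s not in labels.index]
    if missing:
        raise ConfigurationError(f"samples missing from design: {missing}")
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (values - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    zf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    treatments = [TREATMENT_CONTROL, TREATMENT_SPIROPLASMA,
                  TREATMENT_WASP, TREATMENT_BOTH]
    out = {}
    for t in treatments:
        cols = [s for s in expr.columns if labels[s] == t]
        if not cols:
            raise ConfigurationError(f"expression matrix lacks treatment {t}")
        out[t] = zf[cols].mean(axis=1)
    return pd.DataFrame(out)


def _restored_shape(row: pd.Series, delta: float, epsilon: float, sign: int) -> bool:
    """Restored expression shape: wasp shifts the gene by >= delta z-units in
    ``sign`` direction, and the S+wasp mean is back within epsilon of control."""
    shift = sign * (row[TREATMENT_WASP] - row[TREATMENT_CONTROL])
    back = abs(row[TREATMENT_BOTH] - row[TREATMENT_CONTROL])
    return shift >= delta and back <= epsilon


def male_gonad_pattern(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    config: RunConfig = RunConfig(),
) -> set:
    """Genes whose treatment-mean z-scores follow S-W- > S-wasp > S+W- = S+wasp.

    The pattern of male-biased transcripts: near-absent in both
    Spiroplasma-infected (male-free) treatments, intermediate under wasp
    parasitism alone. Thresholds: each '>' requires a gap >= delta z-units,
    '=' requires agreement within epsilon.
    """
    zm = zscore_treatment_means(expr, design)
    flagged = set()
    for gene, row in zm.iterrows():
        if (
            row[TREATMENT_CONTROL] - row[TREATMENT_WASP] >= config.delta
            and row[TREATMENT_WASP]
            - max(row[TREATMENT_SPIROPLASMA], row[TREATMENT_BOTH]) >= config.delta
            and abs(row[TREATMENT_SPIROPLASMA] - row[TREATMENT_BOTH]) <= config.epsilon
        ):
            flagged.add(gene)
    return flagged


def classify_groups(
    partition: VennPartition,
    expr: pd.DataFrame,
    design: pd.DataFrame,
    config: RunConfig = RunConfig(),
) -> list[GroupAssignment]:
    """Assign Venn-region genes to Groups A/B/C or the male-gonad pattern.

    A: green-exclusive-down and red-exclusive-up (restored, wasp-raised).
    B: green-exclusive-up and red-exclusive-down (restored, wasp-lowered);
       blue∩green-up genes with the restored shape are annotated "B-like".
    C: up in green (green_only or red_green) with S+wasp mean exceeding
       every other treatment mean by >= delta while those three means lie
       within epsilon of each other.
    Genes in no group but matching the male-gonad ordering are flagged as
    such; everything else is unclassified.
    """
    zm = zscore_treatment_means(expr, design)
    up = partition.regions.get("up", {})
    down = partition.regions.get("down", {})
    gonad = male_gonad_pattern(expr, design, config)
    assignments = []
    all_genes = sorted(set(up) | set(down))
    for gene in all_genes:
        up_region = up.get(gene)
        down_region = down.get(gene)
        evidence = []
        if up_region:
            evidence.append(f"up:{up_region}")
        if down_region:
            evidence.append(f"down:{down_region}")
        group = "unclassified"
        if down_region == "green_only" and up_region == "red_only":
            group = "A"
        elif up_region == "green_only" and down_region == "red_only":
            group = "B"
        elif gene in zm.index and up_region in ("green_only", "red_green"):
            row = zm.loc[gene]
            others = [row[TREATMENT_CONTROL], row[TREATMENT_SPIROPLASMA],
                      row[TREATMENT_WASP]]
            if (
                row[TREATMENT_BOTH] - max(others) >= config.delta
                and max(others) - min(others) <= config.epsilon
            ):
                group = "C"
        if group == "unclassified" and up_region == "blue_green" and gene in zm.index:
            if _restored_shape(zm.loc[gene], config.delta, config.epsilon, sign=-1):
                evidence.append("B-like")
        if group == "unclassified" and gene in gonad:
            group = "male_gonad_pattern"
        if group == "C":
            evidence.append("peak:S+wasp")
        assignments.append(
            GroupAssignment(gene_id=gene, group=group, evidence=";".join(evidence))
        )
    return assignments


def cluster_view(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    genes: Sequence[str],
    n_clusters: int = 3,
) -> pd.DataFrame:
    """Average-linkage clustering of candidate genes on treatment-mean
    z-scores: the heatmap-style companion view to the threshold
    classifiers (it is deliberately *not* the classifier — cluster identity
    depends on the gene set supplied).

    Returns a frame with the z-means, a cluster label per gene, and the
    dendrogram leaf order.
    """
    from scipy.cluster import hierarchy

    zm = zscore_treatment_means(expr, design).loc[list(genes)]
    if len(zm) < 2:
        out = zm.copy()
        out["cluster"] = 1
        out["leaf_order"] = range(len(out))
        return out
    link = hierarchy.linkage(zm.to_numpy(), method="average")
    labels = hierarchy.fcluster(link, t=min(n_clusters, len(zm)),
                                criterion="maxclust")
    order = hierarchy.leaves_list(link)
    out = zm.copy()
    out["cluster"] = labels
    out["leaf_order"] = np.argsort(order)
    return out


# ---------------------------------------------------------------------------
# Row aggregation for nucleotide-identical genes
# ---------------------------------------------------------------------------

def aggregate_identical_genes(
    counts: pd.DataFrame, groups: dict[str, Sequence[str]]
) -> pd.DataFrame:
    """Sum the rows of nucleotide-identical genes under one label
    (e.g. RIP3, RIP4, RIP5 -> "RIP3-5"); untouched genes pass through.
    Groups must be disjoint."""
    seen: set = set()
    for label, members in groups.items():
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"gene(s) {sorted(overlap)} appear in multiple groups")
        seen.update(members)
    out = counts.copy()
    new_rows = {}
    for label, members in groups.items():
        members = list(members)
        missing = [m for m in members if m not in counts.index]
        if missing:
            raise ValueError(f"group {label!r}: genes absent from matrix: {missing}")
        new_rows[label] = counts.loc[members].sum(axis=0)
        out = out.drop(index=members)
    if new_rows:
        out = pd.concat([out, pd.DataFrame(new_rows).T])
    return out
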