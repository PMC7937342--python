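"""Self-contained validation experiments over the pipeline.

Each function regenerates its inputs with the synthetic-data module, runs
the relevant pipeline stage from scratch, and returns summary numbers.
They back both the acceptance test suite and ``scripts/acceptance.py``.
Problem sizes (replicate counts, simulation counts) are chosen to keep
Monte-Carlo error comfortably inside the bands being checked while staying
desk-scale; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import depurination as dep
from . import interaction as inter
from . import simulate as sim
from .io_formats import RunConfig
from .power import required_n


def power_endpoints() -> dict:
    """The four replicate requirements at 93% power, 2-fold effect,
    alpha 0.05: (depth, cv) in {100, 20} x {0.3, 0.4}."""
    out = {}
    for depth, cv in [(100, 0.3), (100, 0.4), (20, 0.3), (20, 0.4)]:
        n_real, n_int = required_n(depth, cv, effect=2, alpha=0.05, power=0.93)
        out[f"n_{depth}x_bcv{cv}"] = {"real": n_real, "rounded": n_int}
    return out


def wilson_coverage_experiment(
    seed: int,
    rates: tuple = (0.0, 0.05, 0.15, 0.5),
    n_reads: int = 2000,
    n_replicates: int = 200,
    error_rate: float = 1e-3,
) -> dict:
    """Bias and 95% CI coverage of the depurination estimator.

    For each depurination rate d, simulates ``n_replicates`` read sets,
    runs the full caller (anchoring, counting, Wilson interval), and
    records the mean adenine-fraction estimate against the expected
    (1-d)(1-error_rate) plus whether the CI covered it. Coverage is
    reported per rate and pooled over all rates (the pooled figure is the
    calibration summary: per-rate Monte-Carlo error at 200 replicates is
    ~1.5 percentage points).
    """
    per_rate = []
    covered_total = 0
    n_total = 0
    for ri, d in enumerate(rates):
        cfg = sim.ReadSimConfig(seed=seed, n_reads=n_reads,
                                depurination_rate=d, error_rate=error_rate)
        span = dep.locate_srl(cfg.reference)
        truth = (1.0 - d) * (1.0 - error_rate)
        ests, covered = [], 0
        for rep in range(n_replicates):
            reads, _ = sim.simulate_reads(cfg, stream=ri * 100_000 + rep)
            res = dep.assign_reads(reads, cfg.reference, span)
            est = dep.estimate_depurination(dep.count_bases(res.calls, "s"))
            ests.append(est.adenine_fraction)
            covered += est.ci_low <= truth <= est.ci_high
        ests = np.asarray(ests)
        per_rate.append({
            "rate": d,
            "truth": truth,
            "mean_estimate": float(ests.mean()),
            "mc_se": float(ests.std(ddof=1) / np.sqrt(len(ests))),
            "coverage": covered / n_replicates,
        })
        covered_total += covered
        n_total += n_replicates
    return {"per_rate": per_rate, "pooled_coverage": covered_total / n_total}


def _binomial_replicates(rng, proportions, n_reads):
    samples, groups = [], []
    for i, p in enumerate(proportions):
        a = int(rng.binomial(n_reads, p))
        samples.append(dep.SiteBaseCounts(f"s{i}", a=a, t=n_reads - a))
        groups.append("g1" if i < len(proportions) // 2 else "g2")
    return samples, groups


def glm_calibration(
    seed: int,
    n_sim_null: int = 1000,
    n_sim_power: int = 200,
    n_reads: int = 500,
    replicates: int = 4,
    alpha: float = 0.05,
) -> dict:
    """Type-I error and power of the penalized binomial group test.

    Null: both groups at adenine proportion 0.99 (the boundary-adjacent
    regime the penalty exists for); alternative: 0.99 vs 0.80. Also checks
    that complete separation (all-adenine groups) returns finite estimates.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 11)))
    rejections = 0
    for _ in range(n_sim_null):
        samples, groups = _binomial_replicates(
            rng, [0.99] * replicates + [0.99] * replicates, n_reads)
        rejections += dep.compare_depurination(samples, groups).p_value < alpha
    type1 = rejections / n_sim_null

    detections = 0
    for _ in range(n_sim_power):
        samples, groups = _binomial_replicates(
            rng, [0.99] * replicates + [0.80] * replicates, n_reads)
        detections += dep.compare_depurination(samples, groups).p_value < alpha
    power = detections / n_sim_power

    sep_samples = [dep.SiteBaseCounts(f"z{i}", a=n_reads)
                   for i in range(2 * replicates)]
    sep = dep.compare_depurination(
        sep_samples, ["g1"] * replicates + ["g2"] * replicates)
    finite = bool(np.isfinite(sep.group_effect)
                  and np.isfinite(sep.group_effect_se)
                  and np.isfinite(sep.chi_sq))
    return {"type1_error": type1, "power": power,
            "separation_finite": finite, "separation_p": sep.p_value}


def recovery_experiment(seed: int, n_datasets: int = 4) -> dict:
    """Planted-class recovery through DE -> Venn -> group classification.

    Runs ``n_datasets`` independent default count simulations; for each,
    computes the three contrasts with the built-in NB LRT, partitions the
    DE sets, classifies groups, and scores recovery against the truth
    table. Recovery is pooled over the planted Group A/B/C and male-gonad
    genes of all datasets; the false-assignment rate is measured over all
    null genes.
    """
    total = {"planted": 0, "recovered": 0, "null": 0, "false": 0}
    per_class: dict[str, list] = {}
    want = {"group_A": "A", "group_B": "B", "group_C": "C",
            "male_gonad_pattern": "male_gonad_pattern"}
    pattern_groups = set(want.values())
    for k in range(n_datasets):
        cfg = sim.CountSimConfig(seed=seed + 7919 * k)
        counts, design, truth = sim.simulate_counts(cfg)
        contrasts = inter.standard_contrasts(design)
        comps = {name: inter.reference_de(counts, contrasts[name], name)
                 for name in inter.CONTRAST_NAMES}
        partition = inter.venn_partition(comps["blue"], comps["red"],
                                         comps["green"])
        expr = inter.tmm_cpm(counts)
        assigns = inter.classify_groups(partition, expr, design)
        amap = {a.gene_id: a.group for a in assigns}
        tmap = dict(zip(truth.gene_id, truth["class"]))
        for gene, cls in tmap.items():
            if cls in want:
                hit = amap.get(gene) == want[cls]
                total["planted"] += 1
                total["recovered"] += hit
                per_class.setdefault(cls, []).append(hit)
            elif cls == "null":
                total["null"] += 1
                total["false"] += amap.get(gene, "unclassified") in pattern_groups
    return {
        "recovery": total["recovered"] / total["planted"],
        "false_assignment_rate": total["false"] / total["null"],
        "per_class_recovery": {c: float(np.mean(v)) for c, v in per_class.items()},
        "n_planted": total["planted"],
        "n_null": total["null"],
        "n_datasets": n_datasets,
    }


def venn_oracle_check(seed: int, n_instances: int = 100, n_genes: int = 300) -> dict:
    """Region-by-region agreement of venn_partition with brute-force set
    algebra on random DE-set instances."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, 23)))
    genes = [f"g{i}" for i in range(n_genes)]
    mismatches = 0
    for _ in range(n_instances):
        sets, comps = {}, {}
        for name in inter.CONTRAST_NAMES:
            up = set(rng.choice(genes, size=int(rng.integers(0, 80)),
                                replace=False))
            rest = [g for g in genes if g not in up]
            down = set(rng.choice(rest, size=int(rng.integers(0, 80)),
                                  replace=False))
            sets[name] = {"up": up, "down": down}
            comps[name] = inter.DEComparison(name, [
                inter.DEGene(g, 1.0, 0.01) for g in sorted(up)
            ] + [inter.DEGene(g, -1.0, 0.01) for g in sorted(down)])
        p = inter.venn_partition(comps["blue"], comps["red"], comps["green"])
        for direction in ("up", "down"):
            b, r, g = (sets[n][direction] for n in inter.CONTRAST_NAMES)
            oracle = {
                "blue_only": b - r - g, "red_only": r - b - g,
                "green_only": g - b - r, "blue_red": (b & r) - g,
                "blue_green": (b & g) - r, "red_green": (r & g) - b,
                "blue_red_green": b & r & g,
            }
            for region, members in oracle.items():
                if p.genes_in(direction, region) != members:
                    mismatches += 1
    return {"n_instances": n_instances, "region_mismatches": mismatches}
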