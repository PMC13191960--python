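"""Monte-Carlo evaluation of the pipeline on its own synthetic generators:
calibration (false-support under the null), power across amplification and
purity, enrichment-p uniformity, expression-scan power, and NJ recovery.

These are the quantities the package's quality claims rest on; the test
suite and the reproduction script both call into here.
"""
from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .enrichment import permutation_overlap_test
from .expression import ecdna_expression_scan
from .intervals import GenomicInterval
from .phylogeny import neighbor_joining
from .simulate import cis_scenario, simulate_expression, simulate_hic, trans_scenario
from .validation import (
    ValidationConfig,
    build_validation_regions,
    iterative_correction,
    test_cis,
    test_trans,
)


def hic_support_rate(
    kind: str,
    n_replicates: int,
    amplification: float,
    purity: float,
    seed: int,
    config: ValidationConfig | None = None,
) -> float:
    """Fraction of simulated candidate events the Hi-C framework supports.

    ``amplification=1`` gives the null (no signal): the returned rate is then
    the false-support rate. Each replicate simulates an independent contact
    map with one candidate event at a random position, balances it, and runs
    the cis or trans test.
    """
    if kind not in ("cis", "trans"):
        raise ValueError("kind must be 'cis' or 'trans'")
    rng = np.random.default_rng(seed)
    config = config or ValidationConfig()
    maker = cis_scenario if kind == "cis" else trans_scenario
    tester = test_cis if kind == "cis" else test_trans
    supported = testable = 0
    for _ in range(n_replicates):
        scen, event = maker(rng, amplification=amplification, purity=purity)
        matrix = iterative_correction(
            simulate_hic(scen, seed=int(rng.integers(2**31)))
        )
        regions = build_validation_regions(event, [event], matrix.bins, config)
        ev = tester(event, matrix, regions, config)
        if ev.supported is not None:
            testable += 1
            supported += int(ev.supported)
    return supported / testable if testable else float("nan")


def hic_power_curve(
    kind: str,
    amplifications: list[float],
    purities: list[float],
    n_replicates: int,
    seed: int,
) -> dict[str, list[float]]:
    """Support rate along an amplification grid (at the last purity) and a
    purity grid (at the last amplification)."""
    amp_rates = [
        hic_support_rate(kind, n_replicates, a, purities[-1], seed + i)
        for i, a in enumerate(amplifications)
    ]
    pur_rates = [
        hic_support_rate(kind, n_replicates, amplifications[-1], p,
                         seed + 100 + i)
        for i, p in enumerate(purities)
    ]
    return {"amplification": amp_rates, "purity": pur_rates}


def enrichment_null_pvalues(
    n_datasets: int,
    n_perm: int,
    seed: int,
    n_query: int = 100,
    n_peaks: int = 1_400,
    chrom_length: int = 20_000_000,
) -> np.ndarray:
    """Empirical permutation p-values under independent query/peak placement
    (one p per replicate dataset); should be approximately uniform.

    Default dataset sizes put the per-query hit probability near 0.4 so the
    overlap-count statistic spreads over many values — a count statistic with
    few attainable values yields heavily discretized (conservative) p-values
    and uniformity cannot be resolved.
    """
    rng = np.random.default_rng(seed)
    genome = {"chr1": chrom_length}
    out = np.empty(n_datasets)
    for d in range(n_datasets):
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 2_000)
            for s in rng.integers(0, chrom_length - 2_000, n_peaks)
        ]
        query = [
            GenomicInterval("chr1", int(s), int(s) + 5_000)
            for s in rng.integers(0, chrom_length - 5_000, n_query)
        ]
        res = permutation_overlap_test(
            query, peaks, genome, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        out[d] = res.empirical_p
    return out


def expression_scan_power(
    n_replicates: int,
    seed: int,
    n_samples: int = 60,
    beta_ecdna: float = 1.0,
    sigma: float = 0.2,
    n_null_genes: int = 9,
    alpha_fdr: float = 0.05,
) -> tuple[float, float]:
    """(true-gene FDR-hit rate, null-gene FDR-hit rate) over replicates.

    Each replicate scans one gene with a real ecDNA effect alongside
    ``n_null_genes`` CN-only genes.
    """
    rng = np.random.default_rng(seed)
    true_hits = 0
    null_hits = null_total = 0
    for _ in range(n_replicates):
        records = []
        rec, _ = simulate_expression(
            n_samples, beta_ecdna=beta_ecdna, sigma=sigma,
            seed=int(rng.integers(2**31)), gene_id="true",
        )
        records.append(rec)
        for g in range(n_null_genes):
            rec, _ = simulate_expression(
                n_samples, beta_ecdna=0.0, sigma=sigma,
                seed=int(rng.integers(2**31)), gene_id=f"null{g}",
            )
            records.append(rec)
        results = ecdna_expression_scan(records, alpha_fdr)
        for r in results:
            if not r.tested:
                continue
            if r.gene_id == "true":
                true_hits += int(r.fdr < alpha_fdr)
            else:
                null_total += 1
                null_hits += int(r.fdr < alpha_fdr)
    return true_hits / n_replicates, null_hits / max(1, null_total)


def random_additive_tree(
    n_leaves: int, rng: np.random.Generator
) -> tuple[DistanceMatrix, TreeNode]:
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf (additive) distance matrix."""
    labels = [f"L{i}" for i in range(n_leaves)]
    nodes = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        for nd in (a, b):
            nd.length = float(np.round(rng.uniform(0.5, 5.0), 3))
        parent = TreeNode(children=[nodes.pop(j), nodes.pop(i)])
        nodes.append(parent)
    tree = nodes[0]
    d = np.zeros((n_leaves, n_leaves))
    tips = {t.name: t for t in tree.tips()}
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            d[i, j] = d[j, i] = tips[labels[i]].distance(tips[labels[j]])
    return DistanceMatrix(d, ids=labels), tree


def nj_additive_recovery(n_trees: int, seed: int,
                         min_leaves: int = 4, max_leaves: int = 8) -> float:
    """Fraction of random additive matrices whose NJ tree reproduces every
    pairwise distance exactly (within 1e-8)."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_trees):
        n = int(rng.integers(min_leaves, max_leaves + 1))
        dm, _ = random_additive_tree(n, rng)
        tree = neighbor_joining(dm)
        tips = {t.name: t for t in tree.tips()}
        good = all(
            abs(tips[a].distance(tips[b]) - dm[a, b]) < 1e-8
            for ai, a in enumerate(dm.ids)
            for b in dm.ids[ai + 1:]
        )
        ok += int(good)
    return ok / n_trees
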