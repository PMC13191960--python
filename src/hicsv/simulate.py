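"""Synthetic-data generators with known ground truth for every pipeline
stage. The real cohorts behind the method are controlled-access; these
generators emulate their signal structure at desk scale.

Hi-C model
----------
Expected cis counts follow a power-law distance decay modulated by a
purity-mixed chromosomal copy-number multiplier:

    e_ij = B * (|i-j| + 1)^(-alpha) * m_i * m_j,
    m    = purity * cn_chrom / ploidy + (1 - purity)

trans background is ``B * tau * m_i * m_j``; observed counts are Poisson.

An ecDNA event adds contact ONLY to pairs with both bins inside its
segments (the circle interacts with itself, not its former neighborhood):
``+ purity * (A - 1) * B * decay`` cis (``* tau`` for cross-chromosome
pairs), where A is the amplification factor — at purity 1 the intra-event
mean is exactly A times baseline. Event<->flank pairs get no uplift, which
after matrix balancing produces the low-projection ecDNA signature. A BFB
instead amplifies through the chromosomal multiplier (its copies stay on
the chromosome, so event<->flank contact scales too) plus a fold-back
junction hotspot.
"""
from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from skbio import TreeNode

from .contacts import ContactMatrix
from .genome import GenomeBins
from .intervals import GenomicInterval
from .variants import (
    AmpliconEvent,
    Breakpoint,
    CopyNumberSegment,
    CopyNumberSegmentSet,
    MutationMatrix,
)


@dataclass
class SimEvent:
    """Ground-truth cSV embedded in a simulated contact map."""

    event_id: str
    event_class: str  # ecDNA / BFB / linear
    segments: list[GenomicInterval]
    copy_number: float = 20.0
    amplification: float = 10.0  # A: intra-event contact uplift at purity 1

    def to_amplicon_event(self, sample_id: str = "sim") -> AmpliconEvent:
        return AmpliconEvent(
            self.event_id, sample_id, self.event_class,
            [(iv, self.copy_number) for iv in self.segments],
        )


@dataclass
class SimScenario:
    """Study conditions for one simulated Hi-C map."""

    chromsizes: dict[str, int]
    bin_size: int = 10_000
    events: list[SimEvent] = field(default_factory=list)
    purity: float = 0.7
    ploidy: float = 2.0
    decay_exponent: float = 1.0
    base_intensity: float = 200.0
    trans_rate: float = 0.05
    foldback_factor: float = 4.0
    foldback_halfwidth_bins: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        for v in (self.ploidy, self.base_intensity):
            if v <= 0:
                raise ValueError("rates must be positive")
        if self.trans_rate < 0 or self.decay_exponent < 0:
            raise ValueError("rates must be >= 0")


def simulate_hic(scenario: SimScenario, seed: int = 0) -> ContactMatrix:
    """Draw a raw (unbalanced) contact matrix for the scenario."""
    rng = np.random.default_rng(seed)
    bins = GenomeBins(scenario.chromsizes, scenario.bin_size)
    n = bins.n_bins
    rho, psi = scenario.purity, scenario.ploidy

    covered = np.zeros(n, dtype=bool)
    event_bins: list[np.ndarray] = []
    for ev in scenario.events:
        b = np.concatenate([bins.bins_overlapping(iv) for iv in ev.segments])
        if covered[b].any():
            raise ValueError(f"event {ev.event_id} overlaps another event")
        covered[b] = True
        event_bins.append(b)

    # chromosomal multiplier: BFB / linear amplification stays chromosomal
    m = np.ones(n)
    for ev, b in zip(scenario.events, event_bins):
        if ev.event_class in ("BFB", "linear"):
            m[b] = rho * ev.copy_number / psi + (1 - rho)

    expected = np.empty((n, n))
    B, alpha, tau = (scenario.base_intensity, scenario.decay_exponent,
                     scenario.trans_rate)
    same = np.zeros((n, n), dtype=bool)
    idx_all = np.arange(n)
    for c in bins.chrom_names:
        lo, hi = bins.chrom_range(c)
        same[lo:hi, lo:hi] = True
    sep = np.abs(idx_all[:, None] - idx_all[None, :])
    decay = (sep + 1.0) ** (-alpha)
    expected = np.where(same, B * decay, B * tau)
    expected *= np.outer(m, m)

    for ev, b in zip(scenario.events, event_bins):
        if ev.event_class == "ecDNA" and ev.amplification > 1:
            extra = rho * (ev.amplification - 1) * B
            blk = np.ix_(b, b)
            expected[blk] += np.where(same[blk], extra * decay[blk], extra * tau)
        if ev.event_class == "BFB":
            # fold-back hotspot around the last segment's 3' junction
            j = bins.bins_overlapping(ev.segments[-1])[-1]
            w = scenario.foldback_halfwidth_bins
            lo, hi = bins.chrom_range(ev.segments[-1].chrom)
            a = np.arange(max(lo, j - w), min(hi, j + w + 1))
            expected[np.ix_(a, a)] *= scenario.foldback_factor

    upper = np.triu(rng.poisson(expected)).astype(float)
    counts = upper + upper.T - np.diag(np.diag(upper))
    return ContactMatrix(bins, sp.csr_matrix(counts))


# ------------------------------------------------------- cis/trans helpers

def cis_scenario(
    rng: np.random.Generator,
    amplification: float = 10.0,
    purity: float = 0.7,
    n_bins: int = 220,
    event_len_bins: int = 16,
    event_class: str = "ecDNA",
    base_intensity: float = 200.0,
    bin_size: int = 10_000,
) -> tuple[SimScenario, AmpliconEvent]:
    """One single-chromosome candidate event at a random position.

    ``amplification=1`` gives a pure-null matrix: the candidate region
    carries no signal at all.
    """
    margin = event_len_bins + 2  # keep room for full flanks
    start_bin = int(rng.integers(margin, n_bins - event_len_bins - margin))
    iv = GenomicInterval("chr1", start_bin * bin_size,
                         (start_bin + event_len_bins) * bin_size)
    ev = SimEvent("ev1", event_class, [iv], copy_number=20.0,
                  amplification=amplification)
    scen = SimScenario(
        {"chr1": n_bins * bin_size}, bin_size=bin_size, events=[ev],
        purity=purity, base_intensity=base_intensity,
    )
    return scen, ev.to_amplicon_event()


def trans_scenario(
    rng: np.random.Generator,
    amplification: float = 10.0,
    purity: float = 0.7,
    n_bins_per_chrom: int = 120,
    event_len_bins: int = 12,
    base_intensity: float = 200.0,
    trans_rate: float = 0.05,
    bin_size: int = 10_000,
) -> tuple[SimScenario, AmpliconEvent]:
    """A two-chromosome candidate ecDNA (category 3), e.g. chr18+chrX."""
    margin = event_len_bins + 2
    segs = []
    for chrom in ("chr18", "chrX"):
        s = int(rng.integers(margin, n_bins_per_chrom - event_len_bins - margin))
        segs.append(GenomicInterval(chrom, s * bin_size,
                                    (s + event_len_bins) * bin_size))
    ev = SimEvent("ev1", "ecDNA", segs, copy_number=20.0,
                  amplification=amplification)
    scen = SimScenario(
        {"chr18": n_bins_per_chrom * bin_size,
         "chrX": n_bins_per_chrom * bin_size},
        bin_size=bin_size, events=[ev], purity=purity,
        base_intensity=base_intensity, trans_rate=trans_rate,
    )
    return scen, ev.to_amplicon_event()


# ---------------------------------------------------------- chromothripsis

def simulate_chromothripsis(
    chrom: str,
    chrom_length: int,
    region: tuple[int, int],
    n_inv: int,
    n_del: int,
    n_switch: int,
    seed: int = 0,
    min_spacing: int = 1_000,
    sample_id: str = "sim",
) -> tuple[list[Breakpoint], CopyNumberSegmentSet]:
    """Exactly n_inv INV and n_del DEL breakpoint pairs (both ends inside
    the region) plus n_switch CN oscillation boundaries (|dCN| = 1)."""
    start, end = region
    n_pos = 2 * (n_inv + n_del)
    grid = np.arange(start + min_spacing, end - min_spacing, min_spacing)
    if len(grid) < n_pos + n_switch:
        raise ValueError(
            f"cannot place {n_pos} breakends + {n_switch} switches in "
            f"{end - start} bp at {min_spacing} bp spacing"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(grid, size=n_pos + n_switch, replace=False)
    bp_pos, switch_pos = chosen[:n_pos], np.sort(chosen[n_pos:])
    rng.shuffle(bp_pos)
    breakpoints = []
    for k in range(n_inv + n_del):
        p1, p2 = sorted(int(p) for p in bp_pos[2 * k:2 * k + 2])
        if k < n_inv:
            breakpoints.append(Breakpoint.make(chrom, p1, "+", chrom, p2, "+"))
        else:
            breakpoints.append(Breakpoint.make(chrom, p1, "+", chrom, p2, "-"))
    cns = [2.0, 3.0]
    bounds = [0, *[int(p) for p in switch_pos], chrom_length]
    segments = [
        CopyNumberSegment(GenomicInterval(chrom, a, b), cns[i % 2])
        for i, (a, b) in enumerate(zip(bounds, bounds[1:]))
    ]
    return breakpoints, CopyNumberSegmentSet(sample_id, segments)


# ----------------------------------------------------------------- cohort

def simulate_cohort(
    n_samples: int,
    shared_groups: list[list[int]] | None = None,
    locus: tuple[str, int, int] = ("chrX", 65_000_000, 70_000_000),
    seed: int = 0,
    min_separation: int = 5_000,
    chrom_length: int = 156_000_000,
) -> tuple[dict[str, list[AmpliconEvent]], dict[str, CopyNumberSegmentSet]]:
    """Per-sample cSVs at a common locus with known shared/independent truth.

    Samples listed together in a ``shared_groups`` entry carry an identical
    event (same boundaries and junction); all other samples get independent
    events whose breakpoints are at least ``min_separation`` bp from every
    other event's.
    """
    rng = np.random.default_rng(seed)
    shared_groups = shared_groups or []
    chrom, lo, hi = locus
    group_of = {}
    for g, members in enumerate(shared_groups):
        for s in members:
            group_of[s] = g
    # every unit amplifies the same locus (footprints overlap heavily) but
    # independent units get boundaries >= min_separation bp apart
    n_units = len(shared_groups) + sum(
        1 for s in range(n_samples) if s not in group_of
    )
    span = hi - lo
    start_grid = np.arange(lo, lo + span // 5, min_separation)
    end_grid = np.arange(hi - span // 5, hi, min_separation)
    starts = rng.choice(start_grid, size=n_units, replace=False)
    ends = rng.choice(end_grid, size=n_units, replace=False)
    lengths = ends - starts

    def _make(sample_id: str, unit: int) -> AmpliconEvent:
        s = int(starts[unit])
        e = int(s + lengths[unit])
        iv = GenomicInterval(chrom, s, e)
        jn = Breakpoint.make(chrom, s, "-", chrom, e, "+")
        return AmpliconEvent("csv1", sample_id, "ecDNA", [(iv, 20.0)], [jn])

    events: dict[str, list[AmpliconEvent]] = {}
    segsets: dict[str, CopyNumberSegmentSet] = {}
    next_unit = len(shared_groups)
    for s in range(n_samples):
        sid = f"S{s:02d}"
        unit = group_of.get(s)
        if unit is None:
            unit = next_unit
            next_unit += 1
        ev = _make(sid, unit)
        events[sid] = [ev]
        iv = ev.intervals[0]
        segs = [
            CopyNumberSegment(GenomicInterval(chrom, 0, iv.start), 2.0),
            CopyNumberSegment(iv, 20.0),
            CopyNumberSegment(GenomicInterval(chrom, iv.end, chrom_length), 2.0),
        ]
        segsets[sid] = CopyNumberSegmentSet(
            sid, segs, purity=float(rng.uniform(0.3, 0.9)), ploidy=2.0
        )
    return events, segsets


# ------------------------------------------------------------- expression

def simulate_expression(
    n: int,
    beta_cn: float = 0.5,
    beta_ecdna: float = 1.0,
    sigma: float = 0.2,
    seed: int = 0,
    gene_id: str = "GENE",
    ecdna_fraction: float = 0.4,
):
    """One gene's expression driven by CN plus an ecDNA effect.

    CN is drawn with a heavier tail in ecDNA-positive samples (deliberate
    confounding so the nested test is genuinely exercised). Returns the
    record and the truth dict.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    rng = np.random.default_rng(seed)
    ecdna = (rng.random(n) < ecdna_fraction).astype(int)
    # guarantee both groups when possible
    if ecdna.sum() == 0:
        ecdna[int(rng.integers(n))] = 1
    elif ecdna.sum() == n:
        ecdna[int(rng.integers(n))] = 0
    cn = 2.0 + rng.gamma(2.0, 1.0, size=n) + ecdna * rng.gamma(2.0, 4.0, size=n)
    expr = 1.0 + beta_cn * cn + beta_ecdna * ecdna + rng.normal(0, sigma, n)
    from .expression import GeneExpressionRecord

    rec = GeneExpressionRecord(
        gene_id, [f"S{i:02d}" for i in range(n)], expr, cn, ecdna
    )
    truth = {"beta_cn": beta_cn, "beta_ecdna": beta_ecdna, "sigma": sigma}
    return rec, truth


# -------------------------------------------------------------- mutations

def simulate_mutations(
    tree_newick: str,
    mutations_per_branch: int = 5,
    seed: int = 0,
    include_germline: bool = False,
) -> tuple[MutationMatrix, str]:
    """Perfect-phylogeny (infinite-sites) mutation matrix along a known tree.

    Every branch of the input tree receives ``mutations_per_branch`` private
    variants; each leaf carries the union over its root path. The returned
    Newick annotates each branch with its mutation count, so leaf-leaf
    Hamming distances are exactly the tree's path lengths (additive).
    """
    tree = TreeNode.read(_io.StringIO(tree_newick))
    leaves = [t.name for t in tree.tips()]
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 leaves")
    rng = np.random.default_rng(seed)  # reserved for variant id shuffling
    variant_sets: dict[int, list[str]] = {}
    counter = 0
    for node in tree.traverse(include_self=False):
        ids = [f"v{counter + k}" for k in range(mutations_per_branch)]
        counter += mutations_per_branch
        variant_sets[id(node)] = ids
        node.length = float(mutations_per_branch)
    variant_ids = [f"v{k}" for k in range(counter)]
    col = {v: k for k, v in enumerate(variant_ids)}
    presence = np.zeros((len(leaves), counter), dtype=np.int8)
    for i, tip in enumerate(tree.tips()):
        node = tip
        while node.parent is not None:
            for v in variant_sets[id(node)]:
                presence[i, col[v]] = 1
            node = node.parent
    order = rng.permutation(counter) if counter else np.arange(0)
    presence = presence[:, order]
    variant_ids = [variant_ids[k] for k in order]
    samples = list(leaves)
    if include_germline:
        presence = np.vstack([presence, np.zeros(counter, dtype=np.int8)])
        samples.append("germline_truth")
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return MutationMatrix(samples, variant_ids, presence), buf.getvalue().strip()
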