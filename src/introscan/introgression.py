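"""Introgression inference: f3 test, window trees, carrier and event calling.

The scan asks, for every 1-Mb window with enough fixed interspecific
SNPs, whether accessions of one species cluster inside the other
species' clade of the window's neighbor-joining tree.  An accession
whose k nearest leaves (patristic distance) are mostly of the other
species is an *intruder*: it carries an other-species-like haplotype in
that window, i.e. an introgressed segment.  Windows are merged into
loci (adjacent called windows, same direction) and loci into events
(same chromosome and direction, gap at most the LD-decay distance).

Genome-wide evidence of admixture comes from the three-population f3
statistic ``E[(c-a)(c-b)]`` with the finite-sample heterozygosity
correction applied to the target, and a block-jackknife Z-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

from .model import MISSING, GenotypeMatrix, SampleInfo, Window, tile_windows
from .popdiff import allele_counts, identify_fixed_snps
from .sim import A_TO_B, B_TO_A

CALL_NONE = "none"
CALL_BIDIRECTIONAL = "bidirectional"


# -- distances ----------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric allele-sharing distance matrix with accession labels."""

    labels: list[str]
    d: np.ndarray

    def validate(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("negative distances not allowed")


def allele_sharing_distance(
    gm: GenotypeMatrix,
    sites: np.ndarray | None = None,
    sample_idx: np.ndarray | None = None,
) -> DistanceMatrix:
    """Pairwise mean |dosage difference| / 2 over sites called in both.

    A pair with zero shared called sites is an error (no distance is
    defined for it).
    """
    calls = gm.calls
    labels = gm.sample_ids
    if sample_idx is not None:
        sample_idx = np.asarray(sample_idx)
        calls = calls[sample_idx, :]
        labels = [labels[i] for i in sample_idx]
    if sites is not None:
        calls = calls[:, np.asarray(sites)]
    n, m = calls.shape
    if n < 3:
        raise ValueError("need at least 3 samples for a distance matrix")
    if m < 1:
        raise ValueError("need at least 1 site")
    G = calls.astype(np.int16)
    ok = G >= 0
    d = np.zeros((n, n))
    for i in range(n - 1):
        both = ok[i] & ok[i + 1 :]
        shared = both.sum(axis=1)
        if np.any(shared == 0):
            j = i + 1 + int(np.flatnonzero(shared == 0)[0])
            raise ValueError(
                f"no shared called sites for pair ({labels[i]}, {labels[j]})"
            )
        diff = np.abs(G[i] - G[i + 1 :]) * both
        d[i, i + 1 :] = diff.sum(axis=1) / (2.0 * shared)
    d = d + d.T
    return DistanceMatrix(labels=list(labels), d=d)


# -- neighbor joining ---------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Q-criterion ties are broken by the lowest (row, column) index pair in
    the current working matrix (merged nodes replace the lower index).
    Branch lengths are kept as computed (possibly negative); clamp on
    output.  On an additive matrix the generating tree is recovered
    exactly.
    """
    dm.validate()
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dm.d.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]

    while len(nodes) > 3:
        k = len(nodes)
        r = D.sum(axis=1)
        Q = (k - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(k, 1)
        flat = np.full((k, k), np.inf)
        flat[iu] = Q[iu]
        i, j = np.unravel_index(int(np.argmin(flat)), flat.shape)
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = D[i, j] - li
        new = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        dnew = (D[i, :] + D[j, :] - D[i, j]) / 2.0
        # merged node replaces index i; index j is removed
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        keep = np.arange(k) != j
        D = D[np.ix_(keep, keep)]
        nodes[i] = new
        del nodes[j]

    # connect the last three nodes through one internal vertex
    l0 = (D[0, 1] + D[0, 2] - D[1, 2]) / 2.0
    l1 = (D[0, 1] + D[1, 2] - D[0, 2]) / 2.0
    l2 = (D[0, 2] + D[1, 2] - D[0, 1]) / 2.0
    for node, length in zip(nodes, (l0, l1, l2)):
        node.length = float(length)
    return TreeNode(children=list(nodes))


def patristic_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (branch lengths clamped at 0)."""
    t = tree.copy()
    for node in t.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    sk = t.tip_tip_distances()
    return DistanceMatrix(labels=list(sk.ids), d=np.asarray(sk.data, dtype=float))


# -- f3 -----------------------------------------------------------------------

@dataclass
class F3Result:
    target: str
    source1: str
    source2: str
    f3: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    corrected: bool = True

    def is_admixture_signal(self, z_threshold: float = 3.0) -> bool:
        """Negative f3 beyond the Z threshold indicates the target is admixed."""
        return self.f3 < 0 and self.z <= -abs(z_threshold)


def f3_statistic(
    gm: GenotypeMatrix,
    target: str,
    source1: str,
    source2: str,
    block_size_bp: int = 5_000_000,
    correction: bool = True,
) -> F3Result:
    """Three-population statistic f3(target; source1, source2).

    Per usable site (>= 2 called genotypes in every group) the term is
    ``(c - a)(c - b) - c(1 - c)/(nC - 1)`` with sample alt frequencies
    a, b, c and nC called allele copies in the target; the correction
    removes the target's finite-sample heterozygosity bias.  The
    standard error comes from a leave-one-block-out jackknife over
    contiguous genomic blocks, weighted by block site counts.
    """
    counts = {g: allele_counts(gm, g) for g in (target, source1, source2)}
    freqs = {g: c.freq() for g, c in counts.items()}
    usable = np.ones(gm.n_sites, dtype=bool)
    for g in (target, source1, source2):
        usable &= counts[g].called >= 4  # two called diploid genotypes
    if not usable.any():
        raise ValueError("no usable sites: a group lacks called genotypes")
    c_hat = freqs[target]
    a_hat = freqs[source1]
    b_hat = freqs[source2]
    term = (c_hat - a_hat) * (c_hat - b_hat)
    if correction:
        term = term - c_hat * (1 - c_hat) / (counts[target].called - 1.0)

    # contiguous genomic blocks
    block_key = np.empty(gm.n_sites, dtype=object)
    for i in range(gm.n_sites):
        block_key[i] = (gm.chrom[i], int((gm.pos[i] - 1) // block_size_bp))
    term = term[usable]
    block_key = block_key[usable]
    uniq = list(dict.fromkeys(block_key))
    if len(uniq) < 2:
        raise ValueError("fewer than 2 jackknife blocks; reduce block size")
    block_index = {k: i for i, k in enumerate(uniq)}
    labels = np.array([block_index[k] for k in block_key])
    g = len(uniq)
    n = term.size
    total = term.sum()
    m = np.bincount(labels, minlength=g).astype(float)
    block_sums = np.bincount(labels, weights=term, minlength=g)

    theta = total / n
    theta_del = (total - block_sums) / (n - m)
    h = n / m
    theta_j = g * theta - np.sum((1.0 - m / n) * theta_del)
    tau = h * theta - (h - 1.0) * theta_del
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    return F3Result(
        target=target,
        source1=source1,
        source2=source2,
        f3=float(theta),
        se=se,
        z=float(theta / se) if se > 0 else float("nan"),
        n_blocks=g,
        n_sites=int(n),
        corrected=correction,
    )


# -- window scan --------------------------------------------------------------

@dataclass
class WindowScanResult:
    window: Window
    n_snps: int
    n_fixed: int
    assessable: bool
    call: str  # none / A->B / B->A / bidirectional
    intruders_into_a: frozenset[str] = field(default_factory=frozenset)
    intruders_into_b: frozenset[str] = field(default_factory=frozenset)
    tree: TreeNode | None = None

    def has_direction(self, direction: str) -> bool:
        return self.call == direction or self.call == CALL_BIDIRECTIONAL


def _knn_round(
    pat: DistanceMatrix,
    group_of: dict[str, str],
    species_a: str,
    species_b: str,
    knn: int,
    pool: set[str] | None = None,
) -> tuple[set[str], set[str]]:
    labels = pat.labels
    order_key = {lab: i for i, lab in enumerate(sorted(labels))}
    into_a: set[str] = set()
    into_b: set[str] = set()
    for i, lab in enumerate(labels):
        own = group_of[lab]
        other = species_b if own == species_a else species_a
        neighbours = sorted(
            (pat.d[i, j], order_key[labels[j]], labels[j])
            for j in range(len(labels))
            if j != i and (pool is None or labels[j] in pool)
        )[:knn]
        n_other = sum(1 for _, _, nb in neighbours if group_of[nb] == other)
        if neighbours and n_other > len(neighbours) / 2.0:
            (into_a if own == species_a else into_b).add(lab)
    return into_a, into_b


def _knn_intruders(
    pat: DistanceMatrix,
    group_of: dict[str, str],
    species_a: str,
    species_b: str,
    knn: int,
) -> tuple[set[str], set[str]]:
    """Accessions whose k nearest leaves are mostly of the other species.

    Neighbour ties are broken by label order.  The rule runs in two
    rounds: a first pass over all leaves, then a re-evaluation of every
    accession against the non-intruding core only (first-pass intruders
    removed from the neighbour pool).  The second round stops
    other-species *carriers* from masquerading as an accession's own
    clade -- without it, an accession sitting next to several
    introgressed neighbours of the other species would itself be flagged.
    Returns (A accessions clustering with B, B accessions clustering
    with A).
    """
    into_a, into_b = _knn_round(pat, group_of, species_a, species_b, knn)
    flagged = into_a | into_b
    if not flagged:
        return into_a, into_b
    core = {lab for lab in pat.labels if lab not in flagged}
    if len(core) < knn + 1:
        return into_a, into_b
    return _knn_round(pat, group_of, species_a, species_b, knn, pool=core)


def window_scan(
    gm: GenotypeMatrix,
    species_a: str,
    species_b: str,
    windows: list[Window] | None = None,
    window_size: int = 1_000_000,
    min_fixed: int = 20,
    knn: int = 5,
    keep_trees: bool = False,
) -> list[WindowScanResult]:
    """Per-window NJ-tree intrusion scan between two species groups.

    A window is assessable when it holds at least ``min_fixed`` fixed
    interspecific SNPs (fractional near-fixation rule).  Because
    introgression carriers themselves erode the near-fixation counts --
    a window with several other-species-like accessions can fail the
    plain rule even though the species background is fully divergent --
    the gate is two-pass: when the plain count falls short, the window
    tree is built anyway, intruders are identified, and the fixed SNPs
    are recounted with the intruders excluded; the window is assessable
    iff that background count reaches ``min_fixed``.  A genuinely
    undifferentiated window fails both passes and stays uncalled.

    In assessable windows a neighbor-joining tree over all window SNPs
    (species A and B accessions only) is built from allele-sharing
    distances; an accession is an intruder when more than half of its
    ``knn`` nearest leaves (patristic distance, ties by label) belong to
    the other species.  The window call is A->B when only B accessions
    intrude (they carry A-like haplotypes), B->A when only A accessions
    intrude, bidirectional when both.
    """
    idx_a = gm.group_indices(species_a)
    idx_b = gm.group_indices(species_b)
    if idx_a.size < 3 or idx_b.size < 3:
        raise ValueError("both species need >= 3 accessions")
    if windows is None:
        lengths = {
            c: int(gm.pos[gm.chrom == c].max()) for c in gm.chromosomes()
        }
        windows = tile_windows(lengths, window_size)
    group_of = {s.id: s.group for s in gm.samples}
    sample_idx = np.concatenate([idx_a, idx_b])

    results: list[WindowScanResult] = []
    for w in windows:
        sites = np.flatnonzero(gm.site_mask(w))
        if sites.size == 0:
            results.append(
                WindowScanResult(w, 0, 0, False, CALL_NONE)
            )
            continue
        ca = allele_counts(gm, species_a, sites)
        cb = allele_counts(gm, species_b, sites)
        n_fixed = identify_fixed_snps(ca, cb).n_fixed
        dm = allele_sharing_distance(gm, sites, sample_idx)
        tree = nj_tree(dm)
        pat = patristic_distances(tree)
        into_a, into_b = _knn_intruders(pat, group_of, species_a, species_b, knn)
        if n_fixed < min_fixed and (into_a or into_b):
            # second pass: background divergence with intruders excluded
            sub = gm.subset(sample_idx=sample_idx)
            drop = into_a | into_b
            keep_a = [
                i for i, s in enumerate(sub.samples)
                if s.group == species_a and s.id not in drop
            ]
            keep_b = [
                i for i, s in enumerate(sub.samples)
                if s.group == species_b and s.id not in drop
            ]
            if len(keep_a) >= 2 and len(keep_b) >= 2:
                bg = sub.subset(sample_idx=np.array(keep_a + keep_b))
                n_fixed = identify_fixed_snps(
                    allele_counts(bg, species_a, sites),
                    allele_counts(bg, species_b, sites),
                ).n_fixed
        if n_fixed < min_fixed:
            results.append(
                WindowScanResult(w, int(sites.size), int(n_fixed), False, CALL_NONE)
            )
            continue
        if into_a and into_b:
            call = CALL_BIDIRECTIONAL
        elif into_b:
            call = A_TO_B
        elif into_a:
            call = B_TO_A
        else:
            call = CALL_NONE
        results.append(
            WindowScanResult(
                window=w,
                n_snps=int(sites.size),
                n_fixed=int(n_fixed),
                assessable=True,
                call=call,
                intruders_into_a=frozenset(into_a),
                intruders_into_b=frozenset(into_b),
                tree=tree if keep_trees else None,
            )
        )
    return results


# -- loci and events ----------------------------------------------------------

@dataclass
class IntrogressionLocus:
    interval: Window
    direction: str
    carriers: frozenset[str]
    n_windows: int
    mean_support: float  # mean per-window fraction of locus carriers flagged


@dataclass
class IntrogressionEvent:
    id: str
    direction: str
    interval: Window
    loci: list[IntrogressionLocus]
    carriers: frozenset[str]


def _check_scan_sorted(scan: list[WindowScanResult]) -> None:
    seen: set[str] = set()
    prev_chrom: str | None = None
    for res in scan:
        c = res.window.chrom
        if c != prev_chrom:
            if c in seen:
                raise ValueError("scan windows not sorted by genome position")
            seen.add(c)
            prev_chrom = c
            prev_start = res.window.start
        elif res.window.start < prev_start:
            raise ValueError("scan windows not sorted by genome position")
        else:
            prev_start = res.window.start


def call_loci(
    scan: list[WindowScanResult], carrier_min_frac: float = 0.5
) -> list[IntrogressionLocus]:
    """Merge runs of adjacent same-direction called windows into loci.

    A bidirectional window contributes to runs of both directions.  The
    locus carriers are the accessions flagged as intruders in at least
    ``carrier_min_frac`` of the locus's windows; candidates left with no
    carrier are dropped.
    """
    _check_scan_sorted(scan)
    loci: list[IntrogressionLocus] = []
    for direction in (A_TO_B, B_TO_A):
        run: list[WindowScanResult] = []

        def flush(run: list[WindowScanResult]) -> None:
            if not run:
                return
            from collections import Counter

            counts: Counter[str] = Counter()
            for res in run:
                intruders = (
                    res.intruders_into_b if direction == A_TO_B else res.intruders_into_a
                )
                counts.update(intruders)
            need = carrier_min_frac * len(run)
            carriers = frozenset(s for s, k in counts.items() if k >= need)
            if not carriers:
                return
            support = float(
                np.mean(
                    [
                        sum(
                            1
                            for s in carriers
                            if s
                            in (
                                res.intruders_into_b
                                if direction == A_TO_B
                                else res.intruders_into_a
                            )
                        )
                        / len(carriers)
                        for res in run
                    ]
                )
            )
            loci.append(
                IntrogressionLocus(
                    interval=Window(
                        run[0].window.chrom, run[0].window.start, run[-1].window.end
                    ),
                    direction=direction,
                    carriers=carriers,
                    n_windows=len(run),
                    mean_support=support,
                )
            )

        for res in scan:
            if (
                res.has_direction(direction)
                and run
                and run[-1].window.chrom == res.window.chrom
                and run[-1].window.end == res.window.start
            ):
                run.append(res)
            elif res.has_direction(direction):
                flush(run)
                run = [res]
            else:
                flush(run)
                run = []
        flush(run)
    loci.sort(key=lambda l: (l.interval.chrom, l.interval.start, l.direction))
    return loci


def call_events(
    loci: list[IntrogressionLocus],
    merge_distance_bp: float | None = None,
    fallback_merge_distance_bp: int = 5_000_000,
) -> list[IntrogressionEvent]:
    """Merge same-chromosome, same-direction loci into named events.

    Loci whose gap is at most the merge distance (default: the panel's
    LD-decay distance; fallback 5 Mb when undefined) become one event.
    Events are named ``B_INT<k>`` (direction A->B, i.e. into species B)
    or ``A_INT<k>``, numbered by chromosome then start.
    """
    if merge_distance_bp is None or not np.isfinite(merge_distance_bp):
        merge_distance_bp = fallback_merge_distance_bp
    events: list[IntrogressionEvent] = []
    for direction, prefix in ((A_TO_B, "B_INT"), (B_TO_A, "A_INT")):
        dir_loci = sorted(
            (l for l in loci if l.direction == direction),
            key=lambda l: (l.interval.chrom, l.interval.start),
        )
        groups: list[list[IntrogressionLocus]] = []
        for locus in dir_loci:
            if (
                groups
                and groups[-1][-1].interval.chrom == locus.interval.chrom
                and locus.interval.start - groups[-1][-1].interval.end
                <= merge_distance_bp
            ):
                groups[-1].append(locus)
            else:
                groups.append([locus])
        for k, grp in enumerate(groups, start=1):
            carriers = frozenset().union(*(l.carriers for l in grp))
            events.append(
                IntrogressionEvent(
                    id=f"{prefix}{k}",
                    direction=direction,
                    interval=Window(
                        grp[0].interval.chrom,
                        grp[0].interval.start,
                        grp[-1].interval.end,
                    ),
                    loci=list(grp),
                    carriers=carriers,
                )
            )
    return events


def carrier_matrix(
    loci: list[IntrogressionLocus] | list[IntrogressionEvent],
    samples: list[SampleInfo],
):
    """Binary accession x locus carrier indicators and per-accession counts.

    Returns ``(indicator DataFrame, counts Series)`` indexed by accession
    id.  Carrier sets only ever contain recipient-species accessions, so
    rows of the other species are all zero for a given direction.
    """
    import pandas as pd

    ids = [s.id for s in samples]
    known = set(ids)
    columns: dict[str, np.ndarray] = {}
    for i, item in enumerate(loci):
        unknown = set(item.carriers) - known
        if unknown:
            raise KeyError(f"unknown carrier accession(s): {sorted(unknown)[:5]}")
        name = getattr(item, "id", None) or (
            f"{item.interval.chrom}:{item.interval.start}-{item.interval.end}"
            f":{item.direction}"
        )
        columns[name] = np.array([1 if s in item.carriers else 0 for s in ids])
    indicator = pd.DataFrame(columns, index=ids, dtype=int)
    counts = indicator.sum(axis=1) if len(columns) else pd.Series(0, index=ids)
    return indicator, counts
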