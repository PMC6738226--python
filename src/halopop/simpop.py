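"""Forward-time haploid Wright–Fisher simulator with recombination.

Emulates the statistical structure of a small clonal/recombining
haploid fungal population (of the kind sampled in halophilic *Wallemia*
surveys): ~20 strains drawn from a multi-contig genome of up to ~10
Mbp, with tunable per-base mutation and crossover rates, planted clonal
lineages (near-identical genome copies), designated gene windows from
which equal-length alignments are extracted, and a mating-type locus
segregating in two orientations.

Model
-----
A population of N haploid individuals evolves for G non-overlapping
generations from a monomorphic founder population.  Each birth draws a
crossover count X ~ Poisson(rho * total genome length); X = 0 births
copy a single uniformly chosen parent, X > 0 births recombine two
uniformly chosen parents at X uniform breakpoints, with contigs
segregating as independent linkage groups (each contig independently
starts from either parent).  Mutations per birth ~ Poisson(mu * total
length), placed uniformly; mutation is finite-sites biallelic — the
first hit at a site defines its ALT allele, any further hit toggles the
carrier between REF and ALT — so every segregating site is biallelic.

Internally each individual is a sorted array of positions at which it
differs from a moving baseline; differences fixed in the whole
population are periodically folded into the baseline (a pure speed
optimization with bit-identical output).

All randomness flows through one seeded generator; the draw order is
part of the contract (per birth: crossover count, parent index/indices,
breakpoints + per-contig phases, mutation count, mutation positions),
so a given (config, seed) reproduces byte-identical datasets.
Coordinates are 1-based inclusive everywhere at the interface.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np

from .variants import GenotypeMatrix, Locus, write_vcf
from .treescan import GeneAlignment

_BASES = "ACGT"
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SimConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclasses.dataclass
class SimConfig:
    """Full parameterization of one simulated population.

    Parameters
    ----------
    population_size : number of haploid individuals N.
    genome : contig lengths in bp (contigs are independent linkage groups).
    mu : per-base per-generation mutation probability.
    rho : per-base per-generation crossover probability.
    generations : forward generations from the monomorphic founders.
    sample_size : total strains in the output, including planted clone
        copies.
    clone_spec : (lineage_index, n_copies, lam) triples; lineage_index
        refers to the lineage founders in sampling order, each copy is
        the founder genotype plus Poisson(lam) private mutations.
    gene_windows : (contig_index, start, end) 1-based inclusive windows
        from which alignments are extracted.
    mat_locus : (contig_index, start, end, fraction_inverted) or None.
    min_founder_separation : minimum pairwise SNP distance enforced
        (greedily) between sampled lineage founders, so that planted
        lineages are well separated as in the emulated study design.
    lineage_divergence : expected number of private mutations added to
        each sampled lineage founder (Poisson-distributed, inherited by
        its clone copies).  Emulates deep isolation between lineages —
        the regime where within-lineage differences are tens of SNPs
        but between-lineage differences are thousands — which a
        panmictic Wright-Fisher background alone cannot guarantee.
    seed : RNG seed; identical config + seed => bit-identical output.
    """

    population_size: int
    genome: list[int]
    mu: float
    rho: float
    generations: int
    sample_size: int
    clone_spec: list[tuple[int, int, float]] = dataclasses.field(default_factory=list)
    gene_windows: list[tuple[int, int, int]] = dataclasses.field(default_factory=list)
    mat_locus: tuple[int, int, int, float] | None = None
    min_founder_separation: int = 1000
    lineage_divergence: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.genome:
            raise SimConfigError("genome must contain at least one contig")
        if any(l <= 0 for l in self.genome):
            raise SimConfigError("contig lengths must be positive")
        if self.population_size < 2:
            raise SimConfigError("population_size must be >= 2")
        for name, rate in (("mu", self.mu), ("rho", self.rho)):
            if not 0 <= rate <= 1:
                raise SimConfigError(f"{name} must be in [0, 1]")
        if self.generations < 1:
            raise SimConfigError("generations must be >= 1")
        if self.lineage_divergence < 0:
            raise SimConfigError("lineage_divergence must be >= 0")
        n_copies = sum(c for _, c, _ in self.clone_spec)
        if self.sample_size > self.population_size + n_copies:
            raise SimConfigError(
                "sample_size exceeds population_size + planted clone copies"
            )
        n_founders = self.sample_size - n_copies
        if n_founders < 1:
            raise SimConfigError("sample_size leaves no room for lineage founders")
        for li, c, lam in self.clone_spec:
            if not (0 <= li < n_founders):
                raise SimConfigError(f"clone lineage_index {li} out of range")
            if c < 1 or lam < 0:
                raise SimConfigError("clone_spec needs n_copies >= 1 and lam >= 0")
        spans: list[tuple[int, int, int]] = []
        for c, s, e in self.gene_windows:
            if not (0 <= c < len(self.genome)):
                raise SimConfigError(f"gene window contig {c} out of range")
            if not (1 <= s <= e <= self.genome[c]):
                raise SimConfigError(f"gene window ({c},{s},{e}) out of contig bounds")
            spans.append((c, s, e))
        spans.sort()
        for (c1, s1, e1), (c2, s2, e2) in zip(spans, spans[1:]):
            if c1 == c2 and s2 <= e1:
                raise SimConfigError("gene windows overlap")
        if self.mat_locus is not None:
            c, s, e, f = self.mat_locus
            if not (0 <= c < len(self.genome)):
                raise SimConfigError("mat locus contig out of range")
            if not (1 <= s <= e <= self.genome[c]):
                raise SimConfigError("mat locus out of contig bounds")
            if not 0 <= f <= 1:
                raise SimConfigError("fraction_inverted must be in [0, 1]")

    @property
    def total_length(self) -> int:
        return sum(self.genome)

    @property
    def contig_names(self) -> list[str]:
        return [f"contig_{i + 1:02d}" for i in range(len(self.genome))]

    @staticmethod
    def study_default(seed: int = 0) -> "SimConfig":
        """Demonstration configuration at the emulated study's scale:
        21 strains, a multi-contig ~10 Mbp genome, clonal lineages and
        a mating-type locus inverted in ~4 of 21 strains.

        The mutation and recombination rates are demonstration values
        chosen to yield SNP densities of a few tenths of a percent, not
        biological estimates.
        """
        return SimConfig(
            population_size=200,
            genome=[2_000_000] * 5,
            mu=2e-6,
            rho=1e-6,
            generations=400,
            sample_size=21,
            clone_spec=[(0, 2, 10.0), (1, 3, 10.0), (2, 1, 10.0)],
            gene_windows=[(c, 100_001 + w * 200_000, 125_000 + w * 200_000)
                          for c in range(5) for w in range(4)],
            mat_locus=(0, 1_500_001, 1_530_000, 4 / 21),
            lineage_divergence=2000.0,
            seed=seed,
        )


@dataclasses.dataclass
class SimTruth:
    """Ground-truth labels for a simulated dataset."""

    lineage: dict[str, int]
    inverted: dict[str, bool]
    clone_parent: dict[str, str | None]
    breakpoint_count: int
    genealogy_clades: list[frozenset] | None


@dataclasses.dataclass
class SimulatedDataset:
    """Output bundle of :func:`simulate_population`."""

    config: SimConfig
    genotypes: GenotypeMatrix
    gene_alignments: list[GeneAlignment]
    locus_sequences: dict[str, str]
    truth: SimTruth


# ---------------------------------------------------------------------------
# core simulation
# ---------------------------------------------------------------------------

def _toggle(arr: np.ndarray, hits: np.ndarray) -> np.ndarray:
    """Symmetric difference with parity: double hits in one draw cancel."""
    if hits.size == 0:
        return arr
    pos, counts = np.unique(hits, return_counts=True)
    odd = pos[counts % 2 == 1]
    if odd.size == 0:
        return arr
    return np.setxor1d(arr, odd, assume_unique=False)


def _recombine(
    pa: np.ndarray,
    pb: np.ndarray,
    breakpoints: np.ndarray,
    phases: np.ndarray,
    offsets: np.ndarray,
) -> np.ndarray:
    """Child diff-array from two parents given global breakpoints.

    `phases[c]` is the parent (0/1) supplying the start of contig c.
    A switch list is built so that the parent of global position p is
    A when the number of switch points <= p is even.
    """
    switches: list[int] = []
    parity = 0
    xi = 0
    bps = np.sort(breakpoints)
    n_contigs = len(offsets) - 1
    for c in range(n_contigs):
        start, end = offsets[c], offsets[c + 1]
        if parity != phases[c]:
            switches.append(int(start))
            parity ^= 1
        while xi < len(bps) and bps[xi] < end:
            if bps[xi] >= start:
                switches.append(int(bps[xi]))
                parity ^= 1
            xi += 1
    sw = np.asarray(switches, dtype=np.int64)
    keep_a = pa[np.searchsorted(sw, pa, side="right") % 2 == 0]
    keep_b = pb[np.searchsorted(sw, pb, side="right") % 2 == 1]
    return np.sort(np.concatenate([keep_a, keep_b]))


def simulate_population(config: SimConfig) -> SimulatedDataset:
    """Run the Wright–Fisher simulation and assemble the dataset.

    See the module docstring for the model.  Returns genotypes at the
    sites segregating among the sampled strains, per-window gene
    alignments, per-sample mating-locus sequences with orientation
    truth, and truth labels (lineages, clone parents, inversion flags,
    total crossover count, and — for runs without any crossover — the
    clades of the single true genealogy).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.total_length
    offsets = np.concatenate([[0], np.cumsum(config.genome)]).astype(np.int64)
    N = config.population_size
    mu_total = config.mu * L
    rho_total = config.rho * L

    # reference genome as 0..3 codes
    ref = rng.integers(0, 4, size=L, dtype=np.int8)

    empty = np.empty(0, dtype=np.int64)
    pop: list[np.ndarray] = [empty] * N
    parent_of: list[np.ndarray] = []  # -1 where the birth recombined
    baseline = empty
    breakpoint_count = 0

    for gen in range(config.generations):
        new_pop: list[np.ndarray] = []
        parents = np.full(N, -1, dtype=np.int64)
        for i in range(N):
            ncross = int(rng.poisson(rho_total))
            if ncross == 0:
                p = int(rng.integers(N))
                child = pop[p]
                parents[i] = p
            else:
                pa, pb = (int(x) for x in rng.integers(N, size=2))
                bps = rng.integers(0, L, size=ncross).astype(np.int64)
                phases = rng.integers(0, 2, size=len(config.genome))
                child = _recombine(pop[pa], pop[pb], bps, phases, offsets)
                breakpoint_count += ncross
            nmut = int(rng.poisson(mu_total))
            if nmut:
                hits = rng.integers(0, L, size=nmut).astype(np.int64)
                child = _toggle(child, hits)
            new_pop.append(child)
        pop = new_pop
        parent_of.append(parents)
        if (gen + 1) % 100 == 0 and N > 1:
            common = pop[0]
            for arr in pop[1:]:
                if common.size == 0:
                    break
                common = np.intersect1d(common, arr, assume_unique=True)
            if common.size:
                baseline = np.setxor1d(baseline, common, assume_unique=True)
                pop = [
                    np.setdiff1d(arr, common, assume_unique=True) for arr in pop
                ]

    # ---- sample lineage founders with separation ----
    n_copies_total = sum(c for _, c, _ in config.clone_spec)
    n_founders = config.sample_size - n_copies_total
    order = rng.permutation(N)
    chosen: list[int] = []
    for cand in order:
        arr = pop[cand]
        if all(
            np.setxor1d(arr, pop[f], assume_unique=True).size
            >= config.min_founder_separation
            for f in chosen
        ):
            chosen.append(int(cand))
        if len(chosen) == n_founders:
            break
    if len(chosen) < n_founders:
        # not enough well-separated individuals; fill with the remainder
        for cand in order:
            if int(cand) not in chosen:
                chosen.append(int(cand))
            if len(chosen) == n_founders:
                break

    # ---- build sample set: founders then clone copies ----
    sample_arrays: list[np.ndarray] = [pop[f] for f in chosen]
    if config.lineage_divergence > 0:
        for li in range(n_founders):
            k = int(rng.poisson(config.lineage_divergence))
            if k:
                hits = rng.integers(0, L, size=k).astype(np.int64)
                sample_arrays[li] = _toggle(sample_arrays[li], hits)
    lineage: list[int] = list(range(n_founders))
    clone_parent: list[int | None] = [None] * n_founders
    for li, n_cop, lam in config.clone_spec:
        for _ in range(n_cop):
            k = int(rng.poisson(lam))
            arr = sample_arrays[li]
            if k:
                hits = rng.integers(0, L, size=k).astype(np.int64)
                arr = _toggle(arr, hits)
            sample_arrays.append(arr)
            lineage.append(li)
            clone_parent.append(li)
    n_samples = len(sample_arrays)
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]

    # ---- segregating sites and the genotype matrix ----
    if n_samples and any(a.size for a in sample_arrays):
        allpos, counts = np.unique(
            np.concatenate(sample_arrays), return_counts=True
        )
        seg = allpos[(counts > 0) & (counts < n_samples)]
    else:
        seg = empty
    in_base = np.isin(seg, baseline, assume_unique=True)
    calls = np.zeros((n_samples, seg.size), dtype=np.int16)
    for i, arr in enumerate(sample_arrays):
        calls[i] = (np.isin(seg, arr, assume_unique=True) ^ in_base).astype(np.int16)
    refb = ref[seg]
    altb = (refb + 1 + rng.integers(0, 3, size=seg.size)) % 4
    contig_idx = np.searchsorted(offsets, seg, side="right") - 1
    pos1 = seg - offsets[contig_idx] + 1
    names = config.contig_names
    loci = [
        Locus(names[c], int(p), _BASES[r], (_BASES[a],))
        for c, p, r, a in zip(contig_idx, pos1, refb, altb)
    ]
    genotypes = GenotypeMatrix(
        sample_ids=sample_ids,
        loci=loci,
        calls=calls,
        contigs=list(zip(names, config.genome)),
    )

    # alt bases for non-segregating alt positions (fixed differences),
    # drawn on demand in deterministic iteration order
    alt_cache: dict[int, int] = {int(p): int(a) for p, a in zip(seg, altb)}

    def alt_base(p: int) -> int:
        if p not in alt_cache:
            alt_cache[p] = int((ref[p] + 1 + rng.integers(0, 3)) % 4)
        return alt_cache[p]

    def sample_sequence(arr: np.ndarray, gstart: int, gend: int) -> str:
        """Sequence of [gstart, gend) global coords for one sample."""
        codes = ref[gstart:gend].copy()
        lo, hi = np.searchsorted(baseline, [gstart, gend])
        b_in = baseline[lo:hi]
        lo, hi = np.searchsorted(arr, [gstart, gend])
        a_in = arr[lo:hi]
        alts = np.setxor1d(b_in, a_in, assume_unique=True)
        for p in alts:
            codes[p - gstart] = alt_base(int(p))
        return _BASE_BYTES[codes].tobytes().decode()

    # ---- gene alignments ----
    gene_alignments: list[GeneAlignment] = []
    for w, (c, s, e) in enumerate(config.gene_windows):
        gstart = int(offsets[c] + s - 1)
        gend = int(offsets[c] + e)
        seqs = [sample_sequence(arr, gstart, gend) for arr in sample_arrays]
        gene_alignments.append(
            GeneAlignment(
                gene_id=f"gene_{w + 1:03d}",
                sample_ids=list(sample_ids),
                sequences=seqs,
            )
        )

    # ---- mating-type locus ----
    inverted_flags = [False] * n_samples
    locus_sequences: dict[str, str] = {}
    if config.mat_locus is not None:
        c, s, e, frac = config.mat_locus
        target = round(frac * n_samples)
        lineage_members: dict[int, list[int]] = {}
        for i, li in enumerate(lineage):
            lineage_members.setdefault(li, []).append(i)
        inv_lineages = _closest_subset(
            [len(lineage_members[li]) for li in sorted(lineage_members)], target
        )
        sorted_lineages = sorted(lineage_members)
        for k in inv_lineages:
            for i in lineage_members[sorted_lineages[k]]:
                inverted_flags[i] = True
        gstart = int(offsets[c] + s - 1)
        gend = int(offsets[c] + e)
        span = gend - gstart
        core_lo, core_hi = span // 4, span - span // 4
        for i, arr in enumerate(sample_arrays):
            seq = sample_sequence(arr, gstart, gend)
            if inverted_flags[i]:
                seq = (
                    seq[:core_lo]
                    + reverse_complement(seq[core_lo:core_hi])
                    + seq[core_hi:]
                )
            locus_sequences[sample_ids[i]] = seq

    # ---- true genealogy when no crossover occurred ----
    genealogy = None
    if breakpoint_count == 0:
        genealogy = _pedigree_clades(
            parent_of, chosen, lineage, clone_parent, sample_ids
        )

    truth = SimTruth(
        lineage={sid: li for sid, li in zip(sample_ids, lineage)},
        inverted={sid: f for sid, f in zip(sample_ids, inverted_flags)},
        clone_parent={
            sid: (sample_ids[cp] if cp is not None else None)
            for sid, cp in zip(sample_ids, clone_parent)
        },
        breakpoint_count=breakpoint_count,
        genealogy_clades=genealogy,
    )
    return SimulatedDataset(
        config=config,
        genotypes=genotypes,
        gene_alignments=gene_alignments,
        locus_sequences=locus_sequences,
        truth=truth,
    )


def _closest_subset(sizes: list[int], target: int) -> list[int]:
    """Indices of the subset of `sizes` whose sum is closest to target.

    Deterministic subset-sum DP; among equally close sums the
    lexicographically first index subset is chosen.
    """
    best: dict[int, tuple] = {0: ()}
    for i, sz in enumerate(sizes):
        for tot, subset in sorted(best.items()):
            cand = tot + sz
            if cand not in best:
                best[cand] = subset + (i,)
    achievable = min(best, key=lambda t: (abs(t - target), t))
    return list(best[achievable])


def _pedigree_clades(
    parent_of: list[np.ndarray],
    founders: list[int],
    lineage: list[int],
    clone_parent: list[int | None],
    sample_ids: list[str],
) -> list[frozenset]:
    """Clades of the single true genealogy of a crossover-free run.

    Walks the recorded pedigree backwards; whenever two sampled
    lineages meet in a common ancestor a clade (the union of their
    sample labels) is recorded.  Clone copies are attached as children
    of their founder, so each multi-member lineage is itself a clade.
    """
    clades: list[frozenset] = []
    groups: dict[int, set[str]] = {}
    for li, f in enumerate(founders):
        members = {sample_ids[i] for i in range(len(lineage)) if lineage[i] == li}
        if len(members) > 1:
            clades.append(frozenset(members))
        groups.setdefault(f, set()).update(members)
        # two founders can coincide only if sampled with replacement; they
        # never do (founders are distinct individuals)
    current = dict(groups)
    for parents in reversed(parent_of):
        nxt: dict[int, set[str]] = {}
        for ind, members in current.items():
            p = int(parents[ind])
            if p in nxt:
                merged = nxt[p] | members
                nxt[p] = merged
            else:
                nxt[p] = set(members)
        # record newly-formed clades (a parent reached by >= 2 lineages)
        for p, members in nxt.items():
            if len(members) > 1 and frozenset(members) not in clades:
                contributors = [
                    m for ind, m in current.items() if int(parents[ind]) == p
                ]
                if len(contributors) > 1:
                    clades.append(frozenset(members))
        current = nxt
        if len(current) == 1:
            break
    return clades


# ---------------------------------------------------------------------------
# dataset output
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, out_dir: str) -> dict[str, str]:
    """Write VCF, per-gene aligned FASTAs, mating-locus FASTA and a
    truth TSV under `out_dir`; returns the paths written.

    The VCF round-trips through :func:`halopop.variants.read_vcf`
    without loss.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    vcf_path = os.path.join(out_dir, "variants.vcf")
    write_vcf(dataset.genotypes, vcf_path)
    paths["vcf"] = vcf_path
    gene_dir = os.path.join(out_dir, "genes")
    os.makedirs(gene_dir, exist_ok=True)
    for aln in dataset.gene_alignments:
        p = os.path.join(gene_dir, f"{aln.gene_id}.fasta")
        with open(p, "w") as fh:
            for sid, seq in zip(aln.sample_ids, aln.sequences):
                fh.write(f">{sid}\n{seq}\n")
        paths[aln.gene_id] = p
    if dataset.locus_sequences:
        p = os.path.join(out_dir, "mat_locus.fasta")
        with open(p, "w") as fh:
            for sid, seq in dataset.locus_sequences.items():
                fh.write(f">{sid}\n{seq}\n")
        paths["mat_locus"] = p
    truth_path = os.path.join(out_dir, "truth.tsv")
    with open(truth_path, "w") as fh:
        fh.write("sample\tlineage\tinversion\tclone_parent\n")
        for sid in dataset.genotypes.sample_ids:
            fh.write(
                f"{sid}\t{dataset.truth.lineage[sid]}\t"
                f"{int(dataset.truth.inverted.get(sid, False))}\t"
                f"{dataset.truth.clone_parent[sid] or '.'}\n"
            )
    paths["truth"] = truth_path
    return paths
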