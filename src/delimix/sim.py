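"""Multilocus coalescent simulator with known lineage truth.

Emulates the sampling design of a multi-deme species complex: K demes
related by a rooted history of population splits, sampled at one or more
localities each, genotyped at one maternally inherited haploid locus (the
"mtDNA", with a reduced effective size) plus several biparental diploid
nuclear loci.  Migration can be male-biased: a ``sex_bias`` of 1.0 means
every migrant is male, so the maternal locus experiences zero gene flow
while nuclear loci experience the full configured rate — the mechanism that
produces mitochondrial structure without nuclear structure (the
female-philopatry discordance scenario).

The genealogy process is the structured coalescent in continuous time
(exponential waiting times, no per-generation loop).  Within a deme, each
pair of lineages coalesces at rate ``1 / (2 * Ne_locus)`` per generation
where ``Ne_locus = deme_size * multiplier * ploidy``; so a biparental
diploid locus in a deme of N diploids has ``Ne_locus = 2N`` gene copies'
worth of drift, and a maternal haploid locus with the default multiplier
0.25 has ``Ne_locus = N/4`` — the classic mtDNA scaling.  Lineages migrate
(backwards in time) between coexisting demes at the configured
per-generation rates, scaled by ``(1 - sex_bias)`` for maternal loci.  At
each split time the child demes' lineages merge into the parent deme.

Mutations are sprinkled on the resulting genealogy under Jukes–Cantor over
a finite number of sites: the count on a branch is Poisson with mean
``rate * length_bp * branch_length``, each hit lands on a uniform site and
substitutes a uniform different base.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .formats import GroupMap, GenotypeMatrix, LocusAlignment, MISSING_CODE

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_TIME_CAP = 1e8  # generations; guards against non-coalescing configs


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class DemeTree:
    """Rooted topology of demes with split times in generations.

    ``merges`` is a list of ``(child_a, child_b, parent, time)`` events in
    increasing time order; leaves are demes never appearing as a parent.
    """

    merges: list[tuple[str, str, str, float]]

    def __post_init__(self) -> None:
        last = 0.0
        for a, b, parent, t in self.merges:
            if t <= 0:
                raise ValueError(f"split time for {parent!r} must be > 0")
            if t < last:
                raise ValueError("merges must be in increasing time order")
            last = t
        parents = [m[2] for m in self.merges]
        children = [m[0] for m in self.merges] + [m[1] for m in self.merges]
        for a, b, parent, t in self.merges:
            for child in (a, b):
                if child in parents:
                    child_time = dict(
                        (m[2], m[3]) for m in self.merges
                    )[child]
                    if child_time >= t:
                        raise ValueError(
                            f"child deme {child!r} split at {child_time} is "
                            f"not younger than parent {parent!r} at {t}"
                        )
        self._children = set(children)

    @property
    def leaves(self) -> list[str]:
        parents = {m[2] for m in self.merges}
        out: list[str] = []
        for a, b, _, _ in self.merges:
            for d in (a, b):
                if d not in parents and d not in out:
                    out.append(d)
        if not self.merges:
            return out
        return out

    @property
    def all_demes(self) -> list[str]:
        out = list(self.leaves)
        for _, _, p, _ in self.merges:
            if p not in out:
                out.append(p)
        return out

    @property
    def root(self) -> str:
        if not self.merges:
            raise ValueError("single-deme history has no merges")
        return self.merges[-1][2]

    @classmethod
    def single(cls, name: str = "D1") -> "DemeTree":
        tree = cls(merges=[])
        tree._single = name  # type: ignore[attr-defined]
        return tree

    def leaf_names(self) -> list[str]:
        if not self.merges:
            return [getattr(self, "_single", "D1")]
        return self.leaves


@dataclass
class LocusSpec:
    """One locus: name, ploidy, inheritance, length, per-site mutation rate,
    effective-size multiplier (defaults: 1.0 biparental, 0.25 maternal)."""

    name: str
    ploidy: int = 2
    inheritance: str = "biparental"
    length: int = 600
    mutation_rate: float = 1e-5
    ne_multiplier: float | None = None

    def __post_init__(self) -> None:
        if self.inheritance not in ("maternal", "biparental"):
            raise ValueError("inheritance must be 'maternal' or 'biparental'")
        if self.inheritance == "maternal" and self.ploidy != 1:
            raise ValueError("maternal loci must have ploidy 1")
        if self.mutation_rate < 0:
            raise ValueError("mutation rate must be >= 0")
        if self.ne_multiplier is None:
            self.ne_multiplier = 0.25 if self.inheritance == "maternal" else 1.0


@dataclass
class SimulationConfig:
    """Full study design: deme history, sizes, migration, loci, sampling."""

    deme_tree: DemeTree
    deme_sizes: dict[str, float]
    loci: list[LocusSpec]
    samples_per_locality: int = 10
    locality_to_deme: dict[str, str] | None = None
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    sex_bias: float = 0.0
    seed: int = 0
    time_cap: float = DEFAULT_TIME_CAP

    def __post_init__(self) -> None:
        if not 0.0 <= self.sex_bias <= 1.0:
            raise ValueError("sex_bias must lie in [0, 1]")
        for pair, rate in self.migration.items():
            if rate < 0:
                raise ValueError(f"migration rate for {pair} must be >= 0")
        if self.locality_to_deme is None:
            self.locality_to_deme = {d: d for d in self.deme_tree.leaf_names()}
        known = set(self.deme_tree.leaf_names())
        for loc, deme in self.locality_to_deme.items():
            if deme not in known:
                raise ValueError(
                    f"locality {loc!r} maps to unknown deme {deme!r}"
                )
        for deme in self.deme_tree.all_demes if self.deme_tree.merges else \
                self.deme_tree.leaf_names():
            size = self.deme_sizes.get(deme)
            if size is None:
                raise ValueError(f"no effective size for deme {deme!r}")
            if size <= 0:
                raise SimulationError(
                    f"deme {deme!r} has non-positive effective size; "
                    "lineages there can never coalesce"
                )

    def individuals(self) -> dict[str, str]:
        """individual id -> locality, in deterministic order."""
        out: dict[str, str] = {}
        for loc in self.locality_to_deme:
            for i in range(self.samples_per_locality):
                out[f"{loc}_{i:02d}"] = loc
        return out

    def rng_for(self, locus_name: str, salt: int = 0) -> np.random.Generator:
        """Named per-locus substream: adding a locus does not perturb others."""
        return np.random.default_rng(
            [self.seed & 0x7FFFFFFF, zlib.crc32(locus_name.encode()), salt]
        )


# ---------------------------------------------------------------------------
# genealogy simulation
# ---------------------------------------------------------------------------


@dataclass
class Genealogy:
    """A simulated ultrametric rooted genealogy plus event bookkeeping."""

    tree: dendropy.Tree
    n_migrations: int
    tmrca: float


def _copy_ids_for(config: SimulationConfig, locus: LocusSpec) -> dict[str, str]:
    """copy id -> leaf deme for every sampled gene copy of this locus."""
    out: dict[str, str] = {}
    for ind, loc in config.individuals().items():
        deme = config.locality_to_deme[loc]
        if locus.ploidy == 1:
            out[ind] = deme
        else:
            out[f"{ind}_a"] = deme
            out[f"{ind}_b"] = deme
    return out


def simulate_genealogy(
    config: SimulationConfig,
    locus: LocusSpec,
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Simulate one locus genealogy under the split/migration model.

    Returns an ultrametric rooted :class:`dendropy.Tree` over all sampled
    gene copies, with branch lengths in generations, and the number of
    between-deme migration events experienced by the sampled lineages.
    """
    if rng is None:
        rng = config.rng_for(locus.name)
    mig_scale = (1.0 - config.sex_bias) if locus.inheritance == "maternal" else 1.0

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True

    # lineage bookkeeping: node, age, current deme
    nodes: list[dendropy.Node] = []
    ages: dict[int, float] = {}
    lineage_deme: dict[int, str] = {}
    for cid, deme in _copy_ids_for(config, locus).items():
        node = dendropy.Node(taxon=ns.new_taxon(cid))
        nodes.append(node)
        ages[id(node)] = 0.0
        lineage_deme[id(node)] = deme

    merges = list(config.deme_tree.merges)
    active = set(config.deme_tree.leaf_names())
    t = 0.0
    n_migrations = 0
    merge_idx = 0

    def ne_locus(deme: str) -> float:
        return config.deme_sizes[deme] * locus.ne_multiplier * locus.ploidy

    live = list(nodes)
    while len(live) > 1:
        if t > config.time_cap:
            raise SimulationError(
                f"locus {locus.name!r}: no coalescence by t={t:.3g} "
                f"generations (time cap {config.time_cap:.3g}); "
                "check migration rates and split times"
            )
        # per-deme lineage lists
        by_deme: dict[str, list[dendropy.Node]] = {}
        for node in live:
            by_deme.setdefault(lineage_deme[id(node)], []).append(node)

        coal_rates = {
            d: len(ls) * (len(ls) - 1) / 2.0 / (2.0 * ne_locus(d))
            for d, ls in by_deme.items() if len(ls) >= 2
        }
        mig_rates: dict[tuple[str, str], float] = {}
        if mig_scale > 0:
            for (src, dst), m in config.migration.items():
                if m <= 0 or src not in by_deme or dst not in active:
                    continue
                mig_rates[(src, dst)] = len(by_deme[src]) * m * mig_scale
        total = sum(coal_rates.values()) + sum(mig_rates.values())

        next_merge_t = merges[merge_idx][3] if merge_idx < len(merges) else np.inf
        if total <= 0:
            if not np.isfinite(next_merge_t):
                raise SimulationError(
                    f"locus {locus.name!r}: lineages stranded in isolated "
                    f"demes {sorted(by_deme)} with no remaining splits"
                )
            wait = np.inf
        else:
            wait = rng.exponential(1.0 / total)

        if t + wait >= next_merge_t:
            a, b, parent, t_m = merges[merge_idx]
            merge_idx += 1
            t = t_m
            for node in live:
                if lineage_deme[id(node)] in (a, b):
                    lineage_deme[id(node)] = parent
            active.discard(a)
            active.discard(b)
            active.add(parent)
            continue

        t += wait
        if t > config.time_cap:
            continue  # cap check at loop head raises with the final time
        events = list(coal_rates.items()) + list(mig_rates.items())
        rates = np.array([r for _, r in events])
        pick = rng.choice(len(events), p=rates / rates.sum())
        key = events[pick][0]
        if isinstance(key, str):  # coalescence in deme `key`
            ls = by_deme[key]
            i, j = rng.choice(len(ls), size=2, replace=False)
            left, right = ls[i], ls[j]
            parent_node = dendropy.Node()
            parent_node.add_child(left)
            parent_node.add_child(right)
            left.edge.length = t - ages[id(left)]
            right.edge.length = t - ages[id(right)]
            ages[id(parent_node)] = t
            lineage_deme[id(parent_node)] = key
            live = [n for n in live if n is not left and n is not right]
            live.append(parent_node)
        else:  # migration src -> dst
            src, dst = key
            node = by_deme[src][rng.integers(len(by_deme[src]))]
            lineage_deme[id(node)] = dst
            n_migrations += 1

    root = live[0]
    tree.seed_node = root
    root.edge.length = None
    return Genealogy(tree=tree, n_migrations=n_migrations, tmrca=t)


# ---------------------------------------------------------------------------
# mutation sprinkling
# ---------------------------------------------------------------------------


def sprinkle_mutations(
    genealogy: Genealogy | dendropy.Tree,
    locus: LocusSpec,
    rng: np.random.Generator,
) -> LocusAlignment:
    """Drop Jukes–Cantor mutations on a genealogy and emit the alignment.

    Branch mutation counts are Poisson(rate × length × branch length);
    every hit substitutes a uniformly chosen different base at a uniformly
    chosen site.  Deterministic given the generator state.
    """
    tree = genealogy.tree if isinstance(genealogy, Genealogy) else genealogy
    length = locus.length
    root_seq = rng.integers(0, 4, size=length).astype(np.uint8)
    seqs: dict[str, np.ndarray] = {}

    def descend(node, seq: np.ndarray) -> None:
        for child in node.child_nodes():
            bl = child.edge.length
            if bl is None:
                raise SimulationError("genealogy branch without length")
            child_seq = seq.copy()
            n_mut = rng.poisson(locus.mutation_rate * length * bl)
            for _ in range(n_mut):
                site = rng.integers(length)
                child_seq[site] = (child_seq[site] + 1 + rng.integers(3)) % 4
            if child.is_leaf():
                seqs[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    root = tree.seed_node
    if root.is_leaf():  # single-copy degenerate case
        seqs[root.taxon.label] = root_seq
    else:
        descend(root, root_seq)
    copy_ids = sorted(seqs)
    sequences = [
        BASES[seqs[cid]].tobytes().decode() for cid in copy_ids
    ]
    return LocusAlignment(
        locus.name, copy_ids, sequences,
        ploidy=locus.ploidy, inheritance=locus.inheritance,
    )


# ---------------------------------------------------------------------------
# dataset bundles
# ---------------------------------------------------------------------------


@dataclass
class TruthTable:
    """Known truth for a simulated dataset."""

    individual_to_deme: dict[str, str]
    genealogies: dict[str, Genealogy]

    def deme_partition(self) -> dict[str, frozenset[str]]:
        """deme -> frozenset of individuals."""
        out: dict[str, set[str]] = {}
        for ind, deme in self.individual_to_deme.items():
            out.setdefault(deme, set()).add(ind)
        return {d: frozenset(s) for d, s in out.items()}


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    alignments: dict[str, LocusAlignment]
    genotypes: GenotypeMatrix
    truth: TruthTable
    group_map: GroupMap


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate every configured locus and bundle alignments, the derived
    nuclear genotype matrix, the truth table, and the group map.

    Fully reproducible from ``config.seed``: each locus draws from a named
    substream, and the genotype encoding is deterministic.
    """
    from .admixture import encode_haplotype_alleles
    from .popgen import collapse_haplotypes

    alignments: dict[str, LocusAlignment] = {}
    genealogies: dict[str, Genealogy] = {}
    for locus in config.loci:
        rng = config.rng_for(locus.name)
        gen = simulate_genealogy(config, locus, rng)
        genealogies[locus.name] = gen
        alignments[locus.name] = sprinkle_mutations(gen, locus, rng)

    nuclear = [l for l in config.loci if l.inheritance == "biparental"]
    individuals = list(config.individuals())
    if nuclear:
        partitions = {
            l.name: collapse_haplotypes(alignments[l.name]) for l in nuclear
        }
        genotypes = encode_haplotype_alleles(
            partitions, individuals, [l.name for l in nuclear]
        )
    else:
        genotypes = GenotypeMatrix(
            individuals, [],
            np.empty((len(individuals), 0, 2), int).reshape(
                len(individuals), 0, 2
            ),
        )

    ind_to_loc = config.individuals()
    truth = TruthTable(
        individual_to_deme={
            ind: config.locality_to_deme[loc] for ind, loc in ind_to_loc.items()
        },
        genealogies=genealogies,
    )
    gm = GroupMap(individual_to_locality=dict(ind_to_loc))
    return SimulatedDataset(config, alignments, genotypes, truth, gm)


def concatenate_alignments(
    alignments: list[LocusAlignment], name: str = "mtDNA"
) -> LocusAlignment:
    """Concatenate same-ploidy alignments over a shared copy namespace
    (mirrors concatenating the mitochondrial regions before tree building)."""
    ref = sorted(alignments[0].copy_ids)
    for aln in alignments[1:]:
        if sorted(aln.copy_ids) != ref:
            raise ValueError("alignments to concatenate must share copy ids")
    seq_by_copy = {
        cid: "".join(
            aln.sequences[aln.copy_ids.index(cid)] for aln in alignments
        )
        for cid in ref
    }
    return LocusAlignment(
        name, ref, [seq_by_copy[c] for c in ref],
        ploidy=alignments[0].ploidy, inheritance=alignments[0].inheritance,
    )
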