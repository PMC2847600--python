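"""Readers, writers and in-memory containers for the pipeline's formats.

The pipeline moves four kinds of data around:

* :class:`LocusAlignment` — an aligned set of gene copies for one locus,
  haploid (one copy per individual, e.g. a maternally inherited mtDNA
  region) or diploid (two phased allele copies per individual, named with
  ``_a``/``_b`` suffixes).  Stored as FASTA.
* :class:`TreeCollection` — a weighted set of rooted trees sharing one tip
  namespace: a bootstrap sample, an imported posterior sample, or a set of
  per-locus consensus trees.  Stored as one newick string per line.
* :class:`GroupMap` — the individual → locality → hypothesized-lineage
  mapping that defines the groups every downstream statistic is computed
  for.  Stored as TSV.
* genotype matrices in the two STRUCTURE text dialects (two rows per
  individual, or two columns per locus), missing data coded ``-9``.

All readers validate eagerly and raise :class:`FormatError` on truncated or
inconsistent input rather than returning partial data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGT-N")
MISSING_CODE = -9

DIPLOID_SUFFIXES = ("_a", "_b")


class FormatError(ValueError):
    """Malformed or inconsistent input data."""


def copy_to_individual(copy_id: str) -> str:
    """Map an allele-copy id to its individual (strip an ``_a``/``_b`` suffix)."""
    for suf in DIPLOID_SUFFIXES:
        if copy_id.endswith(suf):
            return copy_id[: -len(suf)]
    return copy_id


@dataclass
class LocusAlignment:
    """Aligned sequences for one locus with ploidy and individual metadata.

    Parameters
    ----------
    name :
        Locus name.
    copy_ids :
        One id per row; for diploid loci these carry ``_a``/``_b`` suffixes.
    sequences :
        Equal-length strings over ``A C G T - N``.
    ploidy :
        1 (haploid) or 2 (diploid).
    inheritance :
        ``"maternal"`` or ``"biparental"``.
    """

    name: str
    copy_ids: list[str]
    sequences: list[str]
    ploidy: int = 2
    inheritance: str = "biparental"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError(f"locus {self.name!r}: empty alignment")
        length = len(self.sequences[0])
        for cid, seq in zip(self.copy_ids, self.sequences):
            if len(seq) != length:
                raise FormatError(
                    f"locus {self.name!r}: ragged alignment at record {cid!r} "
                    f"({len(seq)} vs {length} columns)"
                )
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"locus {self.name!r}: illegal character(s) "
                    f"{sorted(bad)} in record {cid!r}"
                )
        if len(set(self.copy_ids)) != len(self.copy_ids):
            seen: set[str] = set()
            for cid in self.copy_ids:
                if cid in seen:
                    raise FormatError(
                        f"locus {self.name!r}: duplicate copy_id {cid!r}"
                    )
                seen.add(cid)
        if self.ploidy not in (1, 2):
            raise FormatError(f"locus {self.name!r}: ploidy must be 1 or 2")
        counts: dict[str, int] = {}
        for cid in self.copy_ids:
            ind = copy_to_individual(cid)
            counts[ind] = counts.get(ind, 0) + 1
        for ind, c in counts.items():
            if c != self.ploidy:
                raise FormatError(
                    f"locus {self.name!r}: individual {ind!r} has {c} copies, "
                    f"expected {self.ploidy}"
                )

    # -- derived views ----------------------------------------------------

    @property
    def n_copies(self) -> int:
        return len(self.copy_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def individuals(self) -> list[str]:
        """Distinct individual ids in row order of first appearance."""
        out: list[str] = []
        seen: set[str] = set()
        for cid in self.copy_ids:
            ind = copy_to_individual(cid)
            if ind not in seen:
                seen.add(ind)
                out.append(ind)
        return out

    def matrix(self) -> np.ndarray:
        """Sequences as a (copies, sites) uint8 array of ASCII codes."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype=np.uint8
        ).reshape(self.n_copies, self.length)


def read_fasta(
    path, name: str = "locus", ploidy: int | None = None,
    inheritance: str = "biparental",
) -> LocusAlignment:
    """Read an aligned FASTA into a :class:`LocusAlignment`.

    Headers follow the ``individual|copy`` convention for diploid data; a
    bare header is taken as the copy id, with the individual derived by
    stripping an ``_a``/``_b`` suffix.  Ploidy is inferred from copy counts
    when not given.
    """
    copy_ids: list[str] = []
    seqs: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        copy_id = header.split("|", 1)[1] if "|" in header else header
        copy_ids.append(copy_id)
        seqs.append(str(rec.seq).upper())
    if not copy_ids:
        raise FormatError(f"{path}: no FASTA records")
    if ploidy is None:
        ploidy = 2 if any(
            cid.endswith(DIPLOID_SUFFIXES) for cid in copy_ids
        ) else 1
    return LocusAlignment(name, copy_ids, seqs, ploidy, inheritance)


def write_fasta(aln: LocusAlignment, path) -> None:
    """Write a :class:`LocusAlignment` as FASTA (``individual|copy`` headers
    for diploid loci)."""
    records = []
    for cid, seq in zip(aln.copy_ids, aln.sequences):
        header = f"{copy_to_individual(cid)}|{cid}" if aln.ploidy == 2 else cid
        records.append(SeqRecord(Seq(seq), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# tree collections
# ---------------------------------------------------------------------------


@dataclass
class TreeCollection:
    """A weighted set of rooted trees sharing one tip namespace.

    ``trees`` is a :class:`dendropy.TreeList` over a single taxon
    namespace; ``weights`` default to equal.  ``source`` tags where the
    collection came from (``bootstrap``, ``imported-posterior``,
    ``consensus-set``); ``flags`` records degeneracies such as star trees
    built from invariant alignments.
    """

    trees: dendropy.TreeList
    weights: np.ndarray | None = None
    source: str = "bootstrap"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.trees) == 0:
            raise FormatError("empty tree collection")
        if self.weights is None:
            self.weights = np.ones(len(self.trees))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.trees):
            raise FormatError("one weight per tree required")
        if np.any(self.weights < 0) or self.weights.sum() <= 0:
            raise FormatError("weights must be >= 0 with positive sum")
        tip_sets = [
            frozenset(lf.taxon.label for lf in t.leaf_node_iter())
            for t in self.trees
        ]
        ref = tip_sets[0]
        for i, ts in enumerate(tip_sets[1:], start=1):
            if ts != ref:
                diff = sorted(ts.symmetric_difference(ref))
                raise FormatError(
                    f"tree {i} tip set differs from tree 0; "
                    f"symmetric difference: {diff}"
                )

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def tip_labels(self) -> frozenset[str]:
        return frozenset(
            lf.taxon.label for lf in self.trees[0].leaf_node_iter()
        )

    def normalized_weights(self) -> np.ndarray:
        return self.weights / self.weights.sum()


def read_newick_collection(path, source: str = "imported-posterior") -> TreeCollection:
    """Read a one-newick-per-line file into a :class:`TreeCollection`.

    Branch lengths and internal-node support labels are preserved.  Inputs
    without an explicit rooting statement are flagged ``unrooted-input`` so
    callers can route them through a rooting operation.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: no trees")
    ns = dendropy.TaxonNamespace()
    trees = dendropy.TreeList(taxon_namespace=ns)
    flags: list[str] = []
    for i, line in enumerate(lines):
        tree = dendropy.Tree.get(
            data=line, schema="newick", preserve_underscores=True, taxon_namespace=ns,
            suppress_internal_node_taxa=True,
        )
        if "[&R]" not in line and "[&r]" not in line:
            if "unrooted-input" not in flags:
                flags.append("unrooted-input")
        tree.is_rooted = True
        trees.append(tree)
    return TreeCollection(trees, source=source, flags=flags)


def write_newick_collection(collection: TreeCollection, path) -> None:
    with open(path, "w") as fh:
        for tree in collection.trees:
            fh.write(
                tree.as_string(
                    schema="newick", unquoted_underscores=True, suppress_rooting=False
                ).strip()
                + "\n"
            )


# ---------------------------------------------------------------------------
# group maps
# ---------------------------------------------------------------------------


@dataclass
class GroupMap:
    """Individual → locality and locality → hypothesized-lineage mapping.

    Group labels live at the individual level; both allele copies of a
    diploid individual inherit the individual's label when statistics are
    computed on copy-level trees.
    """

    individual_to_locality: dict[str, str]
    locality_to_lineage: dict[str, str] = field(default_factory=dict)

    def lineage_of(self, individual: str) -> str | None:
        loc = self.individual_to_locality.get(individual)
        if loc is None:
            return None
        return self.locality_to_lineage.get(loc, loc)

    def individuals_in_localities(self, localities) -> list[str]:
        locs = set(localities)
        return [
            ind for ind, loc in self.individual_to_locality.items()
            if loc in locs
        ]

    def copy_labels(self, copy_ids) -> dict[str, str | None]:
        """Lift individual-level lineage labels to allele-copy ids."""
        return {
            cid: self.lineage_of(copy_to_individual(cid)) for cid in copy_ids
        }

    @property
    def localities(self) -> list[str]:
        seen: list[str] = []
        for loc in self.individual_to_locality.values():
            if loc not in seen:
                seen.append(loc)
        return seen


def read_group_map(path) -> GroupMap:
    """Read a TSV with columns individual, locality[, lineage]."""
    ind_to_loc: dict[str, str] = {}
    loc_to_lin: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError(f"{path}: need at least individual and locality columns")
        for ln in fh:
            if not ln.strip():
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: truncated row {ln!r}")
            ind_to_loc[parts[0]] = parts[1]
            if len(parts) >= 3 and parts[2]:
                loc_to_lin[parts[1]] = parts[2]
    return GroupMap(ind_to_loc, loc_to_lin)


def write_group_map(gm: GroupMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tlocality\tlineage\n")
        for ind, loc in gm.individual_to_locality.items():
            fh.write(f"{ind}\t{loc}\t{gm.locality_to_lineage.get(loc, loc)}\n")


# ---------------------------------------------------------------------------
# genotype matrices (STRUCTURE dialects)
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Integer alleles per (individual, locus, copy); ``-9`` = missing."""

    individuals: list[str]
    loci: list[str]
    alleles: np.ndarray  # (n_ind, n_loci, 2) int
    dialect: str = "two-row"

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        if self.alleles.shape != (len(self.individuals), len(self.loci), 2):
            raise FormatError(
                "allele tensor must be (individuals, loci, 2); got "
                f"{self.alleles.shape}"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def missing_mask(self) -> np.ndarray:
        return self.alleles == MISSING_CODE


def read_genotype_matrix(path) -> GenotypeMatrix:
    """Read a STRUCTURE-style text genotype matrix, auto-detecting dialect.

    Two-row dialect: two consecutive rows per individual, one allele per
    locus per row.  Two-column dialect: one row per individual with two
    consecutive columns per locus.  The detected dialect is recorded on the
    returned object.
    """
    rows: list[tuple[str, list[int]]] = []
    loci: list[str] | None = None
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty genotype file")
        toks = first.split()
        header = not all(_is_int(t) for t in toks[1:]) if len(toks) > 1 else True
        if header:
            loci = toks
        else:
            rows.append((toks[0], [int(t) for t in toks[1:]]))
        for ln in fh:
            if not ln.strip():
                continue
            toks = ln.split()
            try:
                rows.append((toks[0], [int(t) for t in toks[1:]]))
            except ValueError as exc:
                raise FormatError(f"{path}: non-integer allele in {ln!r}") from exc
    if not rows:
        raise FormatError(f"{path}: no genotype rows")
    width = len(rows[0][1])
    for name, vals in rows:
        if len(vals) != width:
            raise FormatError(
                f"{path}: inconsistent locus count in row for {name!r} "
                f"({len(vals)} vs {width})"
            )
    names = [name for name, _ in rows]
    two_row = len(names) == 2 * len(dict.fromkeys(names)) and all(
        names[i] == names[i + 1] for i in range(0, len(names) - 1, 2)
    )
    if two_row:
        if len(names) % 2:
            raise FormatError(f"{path}: odd row count in two-row dialect")
        individuals = names[0::2]
        n_loci = width
        alleles = np.full((len(individuals), n_loci, 2), MISSING_CODE, int)
        for i in range(len(individuals)):
            alleles[i, :, 0] = rows[2 * i][1]
            alleles[i, :, 1] = rows[2 * i + 1][1]
        dialect = "two-row"
    else:
        if width % 2:
            raise FormatError(
                f"{path}: two-column dialect needs an even number of allele "
                f"columns, got {width}"
            )
        individuals = names
        n_loci = width // 2
        alleles = np.array(
            [np.asarray(vals).reshape(n_loci, 2) for _, vals in rows], int
        )
        dialect = "two-column"
    locus_names = (
        loci[-n_loci:] if loci and len(loci) >= n_loci
        else [f"L{i+1}" for i in range(n_loci)]
    )
    return GenotypeMatrix(individuals, locus_names[:n_loci], alleles, dialect)


def write_genotype_matrix(gm: GenotypeMatrix, path, dialect: str | None = None) -> None:
    dialect = dialect or gm.dialect
    with open(path, "w") as fh:
        if dialect == "two-row":
            fh.write("individual\t" + "\t".join(gm.loci) + "\n")
            for i, ind in enumerate(gm.individuals):
                for c in (0, 1):
                    fh.write(
                        ind + "\t"
                        + "\t".join(str(a) for a in gm.alleles[i, :, c])
                        + "\n"
                    )
        elif dialect == "two-column":
            cols = [f"{l}_{s}" for l in gm.loci for s in ("a", "b")]
            fh.write("individual\t" + "\t".join(cols) + "\n")
            for i, ind in enumerate(gm.individuals):
                fh.write(
                    ind + "\t"
                    + "\t".join(str(a) for a in gm.alleles[i].ravel())
                    + "\n"
                )
        else:
            raise FormatError(f"unknown genotype dialect {dialect!r}")


def _is_int(tok: str) -> bool:
    try:
        int(tok)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# misc
# ---------------------------------------------------------------------------


def read_config(path) -> dict[str, str]:
    """Flat ``key = value`` config text; '#' starts a comment."""
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            if "=" not in ln:
                raise FormatError(f"config line without '=': {ln!r}")
            key, val = ln.split("=", 1)
            cfg[key.strip()] = val.strip()
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for key, val in cfg.items():
            fh.write(f"{key} = {val}\n")
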