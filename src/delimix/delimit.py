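"""Concordance rule engine: integrate mtDNA monophyly, nuclear cluster
membership and genealogical-exclusivity significance into lineage diagnoses.

A hypothesized lineage (a locality or set of localities) is *diagnosed* as
an independently evolving population-level lineage when three criteria
concord:

(a) its mtDNA gene copies are monophyletic with probability at least
    ``monophyly_min`` in the mtDNA tree collection — or the lineage is an
    explicitly flagged union of separately monophyletic mtDNA clades
    (``composite-mtDNA-clades``);
(b) its average membership is concentrated (>= ``characteristic_min``) in
    a *characteristic* cluster or small union of clusters, found by adding
    clusters in decreasing order of membership until the threshold is
    reached (at most 4 clusters);
(c) the characteristic clusters show only limited signs of admixture from
    elsewhere: every other lineage with a disjoint locality set
    contributes at most ``foreign_max`` average membership to each of
    them.

Criterion (c) admits one principled exception, *absorption*: a foreign
lineage wholly assigned to my characteristic clusters (combined membership
>= ``characteristic_min``) is not evidence against me when I have
significant genealogical exclusivity (ensemble gsi_T) and it does not, and
at least one third lineage is cleanly excluded from those clusters — the
foreign "lineage" is then read as an over-split piece of mine, not as
admixture.  An explicit per-lineage ``geographic-override`` flag waives
(a) and (c) entirely: it encodes a judgment from information outside the
genetic evidence table (geographic separation of otherwise shared
clusters) and is never inferred.

Finally, a lineage whose locality set strictly contains another diagnosed
lineage's locality set is an *aggregate* of finer diagnosed lineages and is
demoted to not-diagnosed (trace ``superseded-by-finer-partition``).
Lineages without nuclear data get the ``insufficient-data`` verdict.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

FLAG_COMPOSITE = "composite-mtDNA-clades"
FLAG_GEOGRAPHIC = "geographic-override"
KNOWN_FLAGS = {FLAG_COMPOSITE, FLAG_GEOGRAPHIC, "none"}


@dataclass
class Thresholds:
    characteristic_min: float = 0.9
    foreign_max: float = 0.05
    monophyly_min: float = 0.5
    max_union: int = 4

    def __post_init__(self) -> None:
        for name in ("characteristic_min", "foreign_max", "monophyly_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class EvidenceRow:
    """Per-lineage evidence: mtDNA monophyly, membership profile, gsi flag."""

    lineage: str
    localities: frozenset[str]
    mtdna_monophyly: float | None
    profile: dict[int, float]
    gsi_significant: bool = False
    flags: frozenset[str] = frozenset()
    nuclear_data: bool = True
    described_species: bool = False
    nuclear_monophyly: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.flags) - KNOWN_FLAGS
        if unknown:
            raise ValueError(f"unknown override flag(s): {sorted(unknown)}")
        if self.nuclear_data and self.profile:
            total = sum(self.profile.values())
            if not (0.99 - 1e-9 <= total <= 1.01 + 1e-9):
                raise ValueError(
                    f"lineage {self.lineage!r}: membership profile sums to "
                    f"{total:.4f}, expected 1 ± 0.01"
                )

    def membership(self, cluster: int) -> float:
        return self.profile.get(cluster, 0.0)

    def combined(self, clusters) -> float:
        return sum(self.membership(c) for c in clusters)


@dataclass
class Diagnosis:
    lineage: str
    verdict: str  # diagnosed | not-diagnosed | insufficient-data
    characteristic: tuple[int, ...]
    trace: list[str]

    def __post_init__(self) -> None:
        assert self.verdict in ("diagnosed", "not-diagnosed", "insufficient-data")
        if self.verdict == "diagnosed":
            assert self.trace


def characteristic_clusters(
    row: EvidenceRow, thresholds: Thresholds
) -> tuple[int, ...]:
    """Smallest greedy union of clusters reaching ``characteristic_min``.

    Clusters are added in decreasing membership order (ties broken by
    cluster id); an empty tuple means no union of at most ``max_union``
    clusters reaches the threshold.
    """
    order = sorted(row.profile, key=lambda c: (-row.profile[c], c))
    chosen: list[int] = []
    total = 0.0
    for c in order[: thresholds.max_union]:
        chosen.append(c)
        total += row.profile[c]
        if total >= thresholds.characteristic_min - 1e-9:
            return tuple(sorted(chosen))
    return ()


def _disjoint(a: EvidenceRow, b: EvidenceRow) -> bool:
    return not (a.localities & b.localities)


def _mapping_criterion(
    row: EvidenceRow, rows: list[EvidenceRow], thresholds: Thresholds
) -> tuple[bool, tuple[int, ...], list[str]]:
    """Criteria (b) and (c): characteristic-cluster mapping with limited
    admixture.  Returns (holds, characteristic set, trace lines)."""
    trace: list[str] = []
    char = characteristic_clusters(row, thresholds)
    if not char:
        trace.append(
            f"(b) FAIL: no union of <= {thresholds.max_union} clusters reaches "
            f"{thresholds.characteristic_min}"
        )
        return False, char, trace
    trace.append(
        f"(b) pass: characteristic cluster(s) {'+'.join(map(str, char))} "
        f"with combined membership {row.combined(char):.2f}"
    )
    if FLAG_GEOGRAPHIC in row.flags:
        trace.append("(c) waived by geographic-override flag")
        return True, char, trace
    # foreign evidence comes from disjoint non-aggregate rows: a row that
    # strictly contains another row's localities re-describes individuals
    # already represented (with a diluted profile) and is skipped
    def is_aggregate(b: EvidenceRow) -> bool:
        return any(
            c.lineage != b.lineage and c.localities < b.localities
            for c in rows
        )

    others = [
        b for b in rows
        if b.lineage != row.lineage and b.nuclear_data and _disjoint(row, b)
        and not is_aggregate(b)
    ]
    ok = True
    for c in char:
        for b in others:
            if b.membership(c) <= thresholds.foreign_max + 1e-9:
                continue
            if _absorbed(row, b, char, others, thresholds):
                trace.append(
                    f"(c) {b.lineage!r} holds {b.membership(c):.2f} of cluster "
                    f"{c} but is absorbed (wholly assigned here, no "
                    "genealogical exclusivity of its own)"
                )
                continue
            trace.append(
                f"(c) FAIL: {b.lineage!r} has membership "
                f"{b.membership(c):.2f} > {thresholds.foreign_max} in "
                f"characteristic cluster {c}"
            )
            ok = False
    if ok and not any(ln.startswith("(c)") for ln in trace):
        trace.append(
            f"(c) pass: no disjoint lineage exceeds {thresholds.foreign_max} "
            "in the characteristic cluster(s)"
        )
    return ok, char, trace


def _absorbed(
    row: EvidenceRow,
    other: EvidenceRow,
    char: tuple[int, ...],
    others: list[EvidenceRow],
    thresholds: Thresholds,
) -> bool:
    if not row.gsi_significant or other.gsi_significant:
        return False
    if other.combined(char) < thresholds.characteristic_min - 1e-9:
        return False
    # the characteristic clusters must actually separate something
    return any(
        c.lineage != other.lineage
        and c.combined(char) <= thresholds.foreign_max + 1e-9
        for c in others
    )


def diagnose(
    rows: list[EvidenceRow], thresholds: Thresholds | None = None
) -> list[Diagnosis]:
    """Apply the concordance rules to an evidence table.

    Returns one :class:`Diagnosis` per row, in input order, with a full
    rule trace for every verdict.
    """
    thresholds = thresholds or Thresholds()
    out: list[Diagnosis] = []
    for row in rows:
        trace: list[str] = []
        if not row.nuclear_data:
            out.append(
                Diagnosis(
                    row.lineage, "insufficient-data", (),
                    ["no nuclear data for this lineage"],
                )
            )
            continue
        override = FLAG_GEOGRAPHIC in row.flags
        if override:
            mono_ok = True
            trace.append("(a) waived by geographic-override flag")
        elif FLAG_COMPOSITE in row.flags:
            mono_ok = True
            trace.append(
                "(a) pass: lineage is a flagged union of separately "
                "monophyletic mtDNA clades"
            )
        else:
            mono = row.mtdna_monophyly
            mono_ok = mono is not None and mono >= thresholds.monophyly_min - 1e-9
            trace.append(
                f"(a) {'pass' if mono_ok else 'FAIL'}: mtDNA monophyly "
                f"probability {mono if mono is not None else 'NA'} vs "
                f"threshold {thresholds.monophyly_min}"
            )
        map_ok, char, map_trace = _mapping_criterion(row, rows, thresholds)
        trace.extend(map_trace)
        verdict = "diagnosed" if (mono_ok and map_ok) else "not-diagnosed"
        out.append(Diagnosis(row.lineage, verdict, char, trace))

    # aggregate demotion: a strict superset of a diagnosed lineage's
    # localities is an aggregate of finer diagnosed lineages
    diagnosed = {
        d.lineage for d in out if d.verdict == "diagnosed"
    }
    by_name = {r.lineage: r for r in rows}
    for d in out:
        if d.verdict != "diagnosed":
            continue
        mine = by_name[d.lineage].localities
        for other in diagnosed:
            if other == d.lineage:
                continue
            theirs = by_name[other].localities
            if theirs < mine:
                d.verdict = "not-diagnosed"
                d.trace.append(
                    f"superseded-by-finer-partition: contains diagnosed "
                    f"lineage {other!r}"
                )
                break
    return out


def n_diagnosed(diagnoses: list[Diagnosis]) -> int:
    return sum(d.verdict == "diagnosed" for d in diagnoses)


def mapping_holds(
    row: EvidenceRow, rows: list[EvidenceRow],
    thresholds: Thresholds | None = None,
) -> bool:
    """Does the characteristic-cluster mapping criterion hold for this row
    (criteria (b) and (c)/override only, aggregates not demoted)?"""
    thresholds = thresholds or Thresholds()
    ok, _, _ = _mapping_criterion(row, rows, thresholds)
    return ok


# ---------------------------------------------------------------------------
# evidence-table construction from pipeline outputs
# ---------------------------------------------------------------------------


def build_evidence_table(
    candidates: dict[str, frozenset[str]],
    monophyly: dict[str, float | None],
    q_post: np.ndarray,
    q_individuals: list[str],
    group_map,
    gsi_p: dict[str, float],
    gsi_alpha: float = 0.05,
) -> list[EvidenceRow]:
    """Assemble evidence rows for hypothesized lineages.

    Parameters
    ----------
    candidates :
        lineage label -> member locality set.
    monophyly :
        lineage -> mtDNA monophyly probability (None when no mtDNA data).
    q_post, q_individuals :
        Post-processed membership matrix and its row namespace.
    group_map :
        :class:`delimix.formats.GroupMap` for locality -> individuals.
    gsi_p :
        lineage -> ensemble gsi_T permutation p-value (absent = untested).
    """
    idx = {ind: i for i, ind in enumerate(q_individuals)}
    rows: list[EvidenceRow] = []
    for lineage, locs in candidates.items():
        members = [
            ind for ind in group_map.individuals_in_localities(locs)
        ]
        genotyped = [ind for ind in members if ind in idx]
        if not genotyped:
            rows.append(
                EvidenceRow(
                    lineage, frozenset(locs), monophyly.get(lineage),
                    {}, nuclear_data=False,
                )
            )
            continue
        mean_q = q_post[[idx[i] for i in genotyped]].mean(axis=0)
        profile = {
            k + 1: float(v) for k, v in enumerate(mean_q) if v > 1e-12
        }
        p = gsi_p.get(lineage)
        rows.append(
            EvidenceRow(
                lineage, frozenset(locs), monophyly.get(lineage), profile,
                gsi_significant=bool(p is not None and p <= gsi_alpha),
            )
        )
    return rows


# ---------------------------------------------------------------------------
# TSV round-trip and the packaged mouse-lemur evidence table
# ---------------------------------------------------------------------------

_COLUMNS = [
    "lineage", "localities", "described_species", "nuclear_data",
    "mtdna_monophyly", "adora3", "eno", "fga", "vwf", "profile",
    "gsi_significant", "flags",
]


def _parse_profile(text: str) -> dict[int, float]:
    out: dict[int, float] = {}
    if text in ("", "NA"):
        return out
    for part in text.split(","):
        c, v = part.split(":")
        out[int(c)] = float(v)
    return out


def read_evidence_table(path_or_handle) -> list[EvidenceRow]:
    """Read an evidence table TSV (schema = the EvidenceRow columns)."""
    if hasattr(path_or_handle, "read"):
        lines = path_or_handle.read().splitlines()
    else:
        with open(path_or_handle) as fh:
            lines = fh.read().splitlines()
    header = lines[0].split("\t")
    if header != _COLUMNS:
        raise ValueError(
            f"evidence table header mismatch: expected {_COLUMNS}, got {header}"
        )
    rows: list[EvidenceRow] = []
    for ln in lines[1:]:
        if not ln.strip():
            continue
        vals = dict(zip(header, ln.split("\t")))
        mono = vals["mtdna_monophyly"]
        flags = frozenset(
            f for f in vals["flags"].split(";") if f and f != "none"
        )
        nuc = vals["nuclear_data"] == "1"
        rows.append(
            EvidenceRow(
                lineage=vals["lineage"],
                localities=frozenset(vals["localities"].split(";")),
                mtdna_monophyly=None if mono == "NA" else float(mono),
                profile=_parse_profile(vals["profile"]),
                gsi_significant=vals["gsi_significant"] == "1",
                flags=flags,
                nuclear_data=nuc,
                described_species=vals["described_species"] == "1",
                nuclear_monophyly={
                    loc: float(vals[loc])
                    for loc in ("adora3", "eno", "fga", "vwf")
                    if vals[loc] not in ("", "NA")
                },
            )
        )
    return rows


def write_evidence_table(rows: list[EvidenceRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in rows:
            profile = ",".join(
                f"{c}:{v:g}" for c, v in sorted(r.profile.items())
            )
            nm = r.nuclear_monophyly
            fh.write(
                "\t".join(
                    [
                        r.lineage,
                        ";".join(sorted(r.localities)),
                        "1" if r.described_species else "0",
                        "1" if r.nuclear_data else "0",
                        "NA" if r.mtdna_monophyly is None
                        else f"{r.mtdna_monophyly:g}",
                        *(
                            f"{nm[l]:g}" if l in nm else "NA"
                            for l in ("adora3", "eno", "fga", "vwf")
                        ),
                        profile or "NA",
                        "1" if r.gsi_significant else "0",
                        ";".join(sorted(r.flags)) or "none",
                    ]
                )
                + "\n"
            )


def load_mouse_lemur_evidence() -> list[EvidenceRow]:
    """The packaged Madagascar mouse-lemur evidence table.

    One row per hypothesized *Microcebus* lineage: mtDNA monophyly
    probability, per-nuclear-locus monophyly probabilities, average
    membership coefficients in the 19 nuclear clusters, ensemble-gsi
    significance, and the explicit composite-clade / geographic override
    flags.  The worked example for the rule engine.
    """
    ref = importlib.resources.files("delimix").joinpath(
        "data/mouse_lemur_evidence.tsv"
    )
    return read_evidence_table(ref.open("r"))
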