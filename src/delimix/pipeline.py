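"""End-to-end orchestration: stats → trees → clustering → gsi → diagnosis.

Runs the full multi-evidence delimitation workflow on a dataset (simulated
or loaded): per-locus summary statistics, bootstrap tree collections and
majority-rule consensus trees per locus (mtDNA regions concatenated
first), an admixture-clustering sweep over K with replicates and Evanno/
posterior-probability K selection, ensemble genealogical sorting indices
for every hypothesized lineage, and finally the concordance rule engine.
When the dataset is simulated, the diagnosed lineages are scored against
the true deme partition (precision / recall).

Hypothesized lineages are generated the way the evidence tables are built
in practice: from the mtDNA consensus tree, every clade whose tip set is
exactly the union of a set of sampling localities proposes that locality
set as a candidate lineage, plus every single locality.  Aggregate
candidates that merely union finer diagnosed candidates are demoted by the
rule engine itself.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field

import dendropy
import numpy as np

from . import __version__
from .admixture import (
    align_cluster_labels,
    fit_admixture,
    postprocess_memberships,
    select_k,
    KSelection,
)
from .delimit import (
    Diagnosis,
    EvidenceRow,
    Thresholds,
    build_evidence_table,
    diagnose,
)
from .formats import GroupMap, LocusAlignment, TreeCollection, copy_to_individual
from .genetrees import bootstrap_trees, majority_rule_consensus, monophyly_probability
from .gsi import gsi_multilocus, GsiReport
from .popgen import LocusSummary, summarize_locus
from .sim import (
    DemeTree,
    LocusSpec,
    SimulatedDataset,
    SimulationConfig,
    concatenate_alignments,
    simulate_dataset,
)

log = logging.getLogger("delimix")


@dataclass
class PipelineSettings:
    """Desk-scale defaults for one full run; every length is configurable."""

    n_bootstrap: int = 60
    k_range: tuple[int, int] = (1, 6)
    mcmc_replicates: int = 3
    burnin: int = 150
    n_iter: int = 250
    n_perm: int = 300
    gsi_alpha: float = 0.05
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0


@dataclass
class PipelineResult:
    summaries: dict[str, LocusSummary]
    consensus_trees: dict[str, dendropy.Tree]
    k_selection: KSelection
    best_k: int
    q_post: np.ndarray
    q_individuals: list[str]
    candidates: dict[str, frozenset[str]]
    monophyly: dict[str, float]
    gsi_reports: dict[str, GsiReport]
    evidence: list[EvidenceRow]
    diagnoses: list[Diagnosis]
    precision: float | None = None
    recall: float | None = None


def mtdna_candidate_lineages(
    consensus: dendropy.Tree, group_map: GroupMap
) -> dict[str, frozenset[str]]:
    """Locality sets proposed by the mtDNA consensus tree.

    A clade proposes the locality set whose sampled copies it contains
    exactly (locality-closed clades); every single locality is always a
    candidate; the all-localities set is dropped (it is the root).
    """
    loc_of = {
        lbl: group_map.individual_to_locality.get(copy_to_individual(lbl))
        for lbl in (lf.taxon.label for lf in consensus.leaf_node_iter())
    }
    copies_per_loc: dict[str, set[str]] = {}
    for lbl, loc in loc_of.items():
        if loc is not None:
            copies_per_loc.setdefault(loc, set()).add(lbl)
    all_locs = set(copies_per_loc)
    candidates: set[frozenset[str]] = {frozenset([l]) for l in all_locs}
    for node in consensus.preorder_internal_node_iter():
        clade = {lf.taxon.label for lf in node.leaf_iter()}
        locs = {loc_of[l] for l in clade if loc_of[l] is not None}
        if locs == all_locs:
            continue
        expected = set().union(*(copies_per_loc[l] for l in locs))
        if clade == expected:
            candidates.add(frozenset(locs))
    return {
        "+".join(sorted(locset)): locset for locset in sorted(
            candidates, key=lambda s: (len(s), sorted(s))
        )
    }


def _sweep_k(
    genotypes, settings: PipelineSettings
) -> tuple[KSelection, int, np.ndarray]:
    """Replicated admixture sweep; returns (selection, best K by posterior
    probability, replicate-averaged aligned Q at best K)."""
    lo, hi = settings.k_range
    hi = min(hi, genotypes.n_individuals)
    table: dict[int, list[float]] = {}
    q_store: dict[int, list[np.ndarray]] = {}
    for k in range(lo, hi + 1):
        for rep in range(settings.mcmc_replicates):
            res = fit_admixture(
                genotypes, k,
                burnin=settings.burnin, n_iter=settings.n_iter,
                seed=settings.seed + 1000 * k + rep, replicate=rep,
            )
            table.setdefault(k, []).append(res.ln_prob_data)
            q_store.setdefault(k, []).append(res.q)
    selection = select_k(table)
    best_k = selection.best_k_pp
    # report the best replicate's Q: averaging replicates smears clusters
    # whenever K exceeds the true number (label matching is ill-defined
    # for near-empty clusters)
    best_rep = int(np.argmax(table[best_k]))
    return selection, best_k, q_store[best_k][best_rep]


def end_to_end(
    dataset: SimulatedDataset,
    settings: PipelineSettings | None = None,
) -> PipelineResult:
    """Run the full pipeline on a dataset bundle.

    Any stage failure propagates with the stage named in the exception
    message.
    """
    settings = settings or PipelineSettings()
    stage = "stats"
    try:
        summaries = {
            name: summarize_locus(aln, f_star_sims=1000, seed=settings.seed)
            for name, aln in dataset.alignments.items()
        }

        stage = "trees"
        maternal = [
            a for a in dataset.alignments.values() if a.inheritance == "maternal"
        ]
        nuclear = [
            a for a in dataset.alignments.values()
            if a.inheritance == "biparental"
        ]
        if not maternal:
            raise ValueError("no maternal (mtDNA) locus in dataset")
        mt_aln = (
            concatenate_alignments(maternal) if len(maternal) > 1 else maternal[0]
        )
        collections: dict[str, TreeCollection] = {}
        consensus: dict[str, dendropy.Tree] = {}
        for aln in [mt_aln] + nuclear:
            coll = bootstrap_trees(
                aln, n_trees=settings.n_bootstrap,
                seed=(settings.seed ^ zlib.crc32(aln.name.encode()))
                & 0x7FFFFFFF,
            )
            collections[aln.name] = coll
            consensus[aln.name] = majority_rule_consensus(coll)

        stage = "candidates"
        candidates = mtdna_candidate_lineages(
            consensus[mt_aln.name], dataset.group_map
        )

        stage = "cluster-sweep"
        selection, best_k, q_mean = _sweep_k(dataset.genotypes, settings)
        q_post = postprocess_memberships(q_mean, floor=0.05)

        stage = "gsi"
        nuc_consensus = {a.name: consensus[a.name] for a in nuclear}
        gsi_reports: dict[str, GsiReport] = {}
        monophyly: dict[str, float] = {}
        mt_tips = collections[mt_aln.name].tip_labels
        for label, locs in candidates.items():
            members = dataset.group_map.individuals_in_localities(locs)
            tips = {t for t in mt_tips if copy_to_individual(t) in set(members)}
            if 2 <= len(tips) < len(mt_tips):
                monophyly[label] = monophyly_probability(
                    collections[mt_aln.name], tips
                )
            n_all = len(dataset.group_map.individual_to_locality)
            if 2 <= len(members) < n_all:
                gsi_reports[label] = gsi_multilocus(
                    nuc_consensus, set(members),
                    n_perm=settings.n_perm, seed=settings.seed,
                    group_label=label,
                )

        stage = "delimit"
        evidence = build_evidence_table(
            candidates, monophyly, q_post,
            list(dataset.genotypes.individuals), dataset.group_map,
            {l: r.p_value for l, r in gsi_reports.items()},
            gsi_alpha=settings.gsi_alpha,
        )
        diagnoses = diagnose(evidence, settings.thresholds)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    precision = recall = None
    if dataset.truth is not None:
        precision, recall = score_against_truth(
            diagnoses, {c: candidates[c] for c in candidates}, dataset
        )
    return PipelineResult(
        summaries=summaries,
        consensus_trees=consensus,
        k_selection=selection,
        best_k=best_k,
        q_post=q_post,
        q_individuals=list(dataset.genotypes.individuals),
        candidates=candidates,
        monophyly=monophyly,
        gsi_reports=gsi_reports,
        evidence=evidence,
        diagnoses=diagnoses,
        precision=precision,
        recall=recall,
    )


def score_against_truth(
    diagnoses: list[Diagnosis],
    candidates: dict[str, frozenset[str]],
    dataset: SimulatedDataset,
) -> tuple[float, float]:
    """Precision/recall of diagnosed locality sets against the true demes.

    A diagnosed lineage is a true positive when its member individuals are
    exactly one true deme's individuals.
    """
    truth_sets = set(dataset.truth.deme_partition().values())
    diagnosed_sets = set()
    for d in diagnoses:
        if d.verdict != "diagnosed":
            continue
        locs = candidates[d.lineage]
        diagnosed_sets.add(
            frozenset(dataset.group_map.individuals_in_localities(locs))
        )
    if not diagnosed_sets:
        return 0.0, 0.0
    tp = len(diagnosed_sets & truth_sets)
    return tp / len(diagnosed_sets), tp / len(truth_sets)


# ---------------------------------------------------------------------------
# canonical study designs
# ---------------------------------------------------------------------------


def default_loci(
    mt_length: int = 800,
    mt_rate: float = 1e-5,
    n_nuclear: int = 4,
    nuc_length: int = 600,
    nuc_rate: float = 3e-6,
) -> list[LocusSpec]:
    """One concatenated-scale mtDNA locus plus biparental nuclear loci."""
    loci = [
        LocusSpec("mtDNA", ploidy=1, inheritance="maternal",
                  length=mt_length, mutation_rate=mt_rate)
    ]
    for i in range(n_nuclear):
        loci.append(
            LocusSpec(f"nuc{i+1}", ploidy=2, inheritance="biparental",
                      length=nuc_length, mutation_rate=nuc_rate)
        )
    return loci


def recovery_config(
    seed: int = 0,
    n_demes: int = 4,
    deme_size: float = 200.0,
    split_mult: float = 5.0,
    samples_per_locality: int = 10,
) -> SimulationConfig:
    """Deep-divergence design: demes split >= ``split_mult * N`` generations
    ago, no migration; the regime where every deme should be recovered."""
    t1 = split_mult * deme_size
    names = [f"D{i+1}" for i in range(n_demes)]
    merges: list[tuple[str, str, str, float]] = []
    level = list(names)
    t = t1
    gen = 0
    while len(level) > 1:
        nxt: list[str] = []
        for i in range(0, len(level) - 1, 2):
            gen += 1
            parent = f"A{gen}"
            merges.append((level[i], level[i + 1], parent, t))
            nxt.append(parent)
        if len(level) % 2:
            nxt.append(level[-1])
        level = nxt
        t *= 2
    sizes = {n: deme_size for n in names}
    sizes.update({m[2]: deme_size for m in merges})
    return SimulationConfig(
        deme_tree=DemeTree(merges),
        deme_sizes=sizes,
        loci=default_loci(),
        samples_per_locality=samples_per_locality,
        seed=seed,
    )


def discordance_config(
    seed: int = 0,
    deme_size: float = 200.0,
    nuclear_migration: float = 0.1,
    samples_per_locality: int = 10,
) -> SimulationConfig:
    """The female-philopatry scenario: two demes, fully male-biased
    migration (sex_bias = 1) at a high nuclear rate — mtDNA sorts into
    reciprocally monophyletic clades while the nuclear genome stays one
    cohesive population."""
    t = 10.0 * deme_size
    merges = [("D1", "D2", "ROOT", t)]
    return SimulationConfig(
        deme_tree=DemeTree(merges),
        deme_sizes={"D1": deme_size, "D2": deme_size, "ROOT": deme_size},
        loci=default_loci(),
        samples_per_locality=samples_per_locality,
        migration={("D1", "D2"): nuclear_migration,
                   ("D2", "D1"): nuclear_migration},
        sex_bias=1.0,
        seed=seed,
    )


def hierarchical_config(
    seed: int = 0,
    deme_size: float = 150.0,
    samples_per_locality: int = 6,
) -> SimulationConfig:
    """Two super-groups of two demes each: shallow splits within, a deep
    split between — the regime where Evanno's ΔK flags the top level K=2.

    The within-supergroup splits are recent (N/2 generations) so the demes
    inside a supergroup stay weakly differentiated; deeper within-splits
    would complete lineage sorting at all four demes and flatten the
    hierarchy into four coordinate clusters.
    """
    shallow = 0.5 * deme_size
    deep = 20.0 * deme_size
    merges = [
        ("D1", "D2", "A1", shallow),
        ("D3", "D4", "A2", shallow),
        ("A1", "A2", "ROOT", deep),
    ]
    sizes = {n: deme_size for n in ("D1", "D2", "D3", "D4", "A1", "A2", "ROOT")}
    return SimulationConfig(
        deme_tree=DemeTree(merges),
        deme_sizes=sizes,
        loci=default_loci(n_nuclear=5),
        samples_per_locality=samples_per_locality,
        seed=seed,
    )


def run_simulated(
    config: SimulationConfig, settings: PipelineSettings | None = None
) -> PipelineResult:
    """Simulate a dataset under ``config`` and run the full pipeline."""
    settings = settings or PipelineSettings(seed=config.seed)
    log.info(
        "delimix %s | run-all | seed=%s | loci=%s | localities=%s",
        __version__, config.seed,
        [l.name for l in config.loci], list(config.locality_to_deme or {}),
    )
    dataset = simulate_dataset(config)
    for name, aln in dataset.alignments.items():
        digest = hashlib.sha256(
            "".join(aln.sequences).encode()
        ).hexdigest()[:12]
        log.info("input digest %s: %s", name, digest)
    return end_to_end(dataset, settings)
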