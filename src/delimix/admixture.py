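"""Bayesian admixture clustering of multilocus genotypes with K selection.

A STRUCTURE-style Gibbs sampler over the admixture model: each individual
i has a membership vector Q_i on the K-simplex, each allele copy at locus
l draws a cluster of origin z from Q_i and then an allele from that
cluster's frequency vector P_{k,l}.  Updates per sweep:

* z | Q, P      — categorical, per allele copy;
* P | z         — Dirichlet-conjugate counts; under the correlated-
                  frequencies model the prior is the F-model,
                  P_{k,l} ~ Dirichlet(p_A,l (1 - F_k) / F_k), with the
                  ancestral frequencies p_A and per-cluster drift F_k
                  updated by random-walk Metropolis;
* Q | z         — Dirichlet(alpha + copy counts);
* alpha         — random-walk Metropolis, uniform(0, 10) prior, one alpha
                  shared across clusters.

The data log-likelihood trace sum_{i,l,c} log sum_k q_ik p_k,l(allele) is
recorded each retained sweep; ln Pr(X|K) is estimated from it as
mean - var/2, the harmonic-style estimator of the clustering program this
sampler emulates.  Model-selection helpers: posterior probability of K
under a uniform prior (softmax over ln Pr(X|K)) and the Evanno second-
difference statistic ΔK.

Missing allele copies (coded -9) are excluded from every update and from
the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .formats import GenotypeMatrix, MISSING_CODE


@dataclass
class ClusterResult:
    """Posterior summaries of one admixture fit at one K."""

    k: int
    replicate: int
    q: np.ndarray                      # (n_ind, K) posterior-mean memberships
    freqs: list[np.ndarray]            # per locus: (K, n_alleles)
    loglik_trace: np.ndarray
    ln_prob_data: float
    alpha_trace: np.ndarray
    seed: int
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert np.allclose(self.q.sum(axis=1), 1.0, atol=1e-9)
        assert np.isfinite(self.ln_prob_data)


def encode_haplotype_alleles(
    partitions: dict[str, dict[str, list[str]]],
    individuals: list[str],
    loci: list[str],
) -> GenotypeMatrix:
    """Bridge sequence loci to a genotype matrix via haplotype classes.

    ``partitions[locus]`` maps haplotype sequence -> copy ids (the output
    of :func:`delimix.popgen.collapse_haplotypes`).  Each distinct
    haplotype per locus gets a stable integer allele (1-based, in
    partition-insertion order); diploid individuals get two alleles per
    locus; individuals with a missing copy get ``-9`` there.
    """
    from .formats import copy_to_individual

    n_ind, n_loci = len(individuals), len(loci)
    ind_index = {ind: i for i, ind in enumerate(individuals)}
    alleles = np.full((n_ind, n_loci, 2), MISSING_CODE, dtype=int)
    for l, locus in enumerate(loci):
        for allele, (hap, copies) in enumerate(partitions[locus].items(), start=1):
            for cid in copies:
                ind = copy_to_individual(cid)
                if ind not in ind_index:
                    continue
                slot = 1 if cid.endswith("_b") else 0
                alleles[ind_index[ind], l, slot] = allele
    return GenotypeMatrix(list(individuals), list(loci), alleles)


def decode_haplotype_alleles(
    gm: GenotypeMatrix, partitions: dict[str, dict[str, list[str]]]
) -> dict[str, dict[int, str]]:
    """Inverse of :func:`encode_haplotype_alleles`: allele int -> haplotype."""
    out: dict[str, dict[int, str]] = {}
    for locus in gm.loci:
        out[locus] = {
            i: hap for i, hap in enumerate(partitions[locus], start=1)
        }
    return out


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------


class AdmixtureModel:
    """STRUCTURE-style admixture clusterer with a scikit-learn flavored API.

    Parameters
    ----------
    n_clusters :
        K, the assumed number of clusters (>= 1).
    burnin, n_iter, thin :
        MCMC schedule; ``n_iter`` sweeps are retained post-burnin, every
        ``thin``-th recorded.
    correlated_freqs :
        Use the F-model prior linking cluster allele frequencies through
        ancestral frequencies and per-cluster drift (on by default,
        matching the model choice for closely related populations).
    alpha_init, alpha_prior_max, alpha_step :
        Admixture-parameter initial value, uniform-prior upper bound, and
        Metropolis step width.
    random_state :
        Seed for the sampler's generator.

    Fitted attributes (trailing underscore): ``Q_`` posterior-mean
    memberships, ``freqs_`` posterior-mean cluster allele frequencies,
    ``loglik_trace_``, ``alpha_trace_``, ``ln_prob_data_``.
    """

    def __init__(
        self,
        n_clusters: int = 2,
        burnin: int = 200,
        n_iter: int = 400,
        thin: int = 1,
        correlated_freqs: bool = True,
        alpha_init: float = 1.0,
        alpha_prior_max: float = 10.0,
        alpha_step: float = 0.1,
        freq_lambda: float = 1.0,
        random_state: int = 0,
    ) -> None:
        self.n_clusters = n_clusters
        self.burnin = burnin
        self.n_iter = n_iter
        self.thin = thin
        self.correlated_freqs = correlated_freqs
        self.alpha_init = alpha_init
        self.alpha_prior_max = alpha_prior_max
        self.alpha_step = alpha_step
        self.freq_lambda = freq_lambda
        self.random_state = random_state

    # minimal sklearn-compatible parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "n_clusters", "burnin", "n_iter", "thin", "correlated_freqs",
                "alpha_init", "alpha_prior_max", "alpha_step", "freq_lambda",
                "random_state",
            )
        }

    def set_params(self, **params) -> "AdmixtureModel":
        for key, val in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, val)
        return self

    # -- fitting ----------------------------------------------------------

    def fit(self, genotypes: GenotypeMatrix) -> "AdmixtureModel":
        k = self.n_clusters
        if k < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.n_iter < 1:
            raise ValueError("n_iter must be > 0")
        if k > genotypes.n_individuals:
            raise ValueError(
                f"K = {k} exceeds the number of individuals "
                f"({genotypes.n_individuals})"
            )
        rng = np.random.default_rng(self.random_state)
        alleles = genotypes.alleles
        n_ind, n_loci, _ = alleles.shape

        kept_loci = []
        for l in range(n_loci):
            if np.all(alleles[:, l, :] == MISSING_CODE):
                continue  # all-missing locus dropped
            kept_loci.append(l)
        self.dropped_loci_ = [
            genotypes.loci[l] for l in range(n_loci) if l not in kept_loci
        ]
        alleles = alleles[:, kept_loci, :]
        n_loci = len(kept_loci)
        if n_loci == 0:
            raise ValueError("no informative loci")

        # recode alleles to 0..J_l-1 per locus
        coded = np.full_like(alleles, -1)
        n_alleles: list[int] = []
        for l in range(n_loci):
            vals = np.unique(alleles[:, l, :])
            vals = vals[vals != MISSING_CODE]
            lookup = {v: j for j, v in enumerate(vals)}
            for v, j in lookup.items():
                coded[:, l, :][alleles[:, l, :] == v] = j
            n_alleles.append(len(vals))
        observed = alleles != MISSING_CODE
        jmax = max(n_alleles)

        # state
        lam = self.freq_lambda
        p = np.zeros((k, n_loci, jmax))
        p_anc = np.zeros((n_loci, jmax))
        for l in range(n_loci):
            j = n_alleles[l]
            p_anc[l, :j] = rng.dirichlet(np.full(j, lam))
            p[:, l, :j] = rng.dirichlet(np.full(j, lam), size=k)
        f_drift = np.full(k, 0.1)
        q = np.full((n_ind, k), 1.0 / k)
        alpha = float(self.alpha_init)

        coded_flat = np.clip(coded, 0, None)
        ii = np.repeat(np.arange(n_ind), n_loci * 2).reshape(n_ind, n_loci, 2)
        ll = np.tile(np.repeat(np.arange(n_loci), 2), n_ind).reshape(
            n_ind, n_loci, 2
        )

        total = self.burnin + self.n_iter
        keep = []
        q_sum = np.zeros_like(q)
        p_sum = np.zeros_like(p)
        loglik_trace = []
        alpha_trace = []
        tiny = 1e-300

        for sweep in range(total):
            # z | Q, P  — probs (i, l, c, k)
            pk = p[:, ll, coded_flat]              # (k, n_ind, n_loci, 2)
            pk = np.moveaxis(pk, 0, -1)            # (n_ind, n_loci, 2, k)
            probs = pk * q[:, None, None, :]
            probs = np.where(observed[..., None], probs, 1.0 / k)
            norm = probs.sum(axis=-1, keepdims=True)
            probs = probs / np.maximum(norm, tiny)
            u = rng.random(probs.shape[:-1])[..., None]
            z = (probs.cumsum(axis=-1) < u).sum(axis=-1)
            z = np.minimum(z, k - 1)

            # P | z
            counts = np.zeros((k, n_loci, jmax))
            zi = z[observed]
            np.add.at(
                counts, (zi, ll[observed], coded_flat[observed]), 1.0
            )
            for kk in range(k):
                for l in range(n_loci):
                    j = n_alleles[l]
                    if self.correlated_freqs:
                        f = np.clip(f_drift[kk], 1e-4, 1 - 1e-4)
                        prior = p_anc[l, :j] * (1.0 - f) / f
                    else:
                        prior = np.full(j, lam)
                    p[kk, l, :j] = rng.dirichlet(prior + counts[kk, l, :j])
                    p[kk, l, j:] = 0.0

            # Q | z
            m = np.zeros((n_ind, k))
            np.add.at(m, (ii[observed], zi), 1.0)
            q = rng.gamma(alpha + m, 1.0)
            q /= q.sum(axis=1, keepdims=True)
            q = np.clip(q, 1e-12, None)
            q /= q.sum(axis=1, keepdims=True)

            # alpha — random-walk Metropolis on log alpha (uniform(0,
            # alpha_prior_max) prior); the log scale mixes down to the
            # small alpha values favored by cleanly separated data
            if k > 1:
                prop = alpha * np.exp(rng.normal(0.0, 3.0 * self.alpha_step))
                if 0.0 < prop < self.alpha_prior_max:
                    logq = np.log(q).sum()
                    cur = n_ind * (gammaln(k * alpha) - k * gammaln(alpha)) \
                        + (alpha - 1.0) * logq
                    new = n_ind * (gammaln(k * prop) - k * gammaln(prop)) \
                        + (prop - 1.0) * logq
                    # log-scale proposal Jacobian: q(a->a')/q(a'->a) = a'/a
                    if np.log(rng.random()) < new - cur + np.log(prop / alpha):
                        alpha = prop

            # F-model hyperparameters
            if self.correlated_freqs:
                self._update_f_model(
                    rng, p, p_anc, f_drift, n_alleles
                )

            if sweep >= self.burnin and (sweep - self.burnin) % self.thin == 0:
                pk = p[:, ll, coded_flat]
                pk = np.moveaxis(pk, 0, -1)
                mix = (pk * q[:, None, None, :]).sum(axis=-1)
                ll_val = float(
                    np.log(np.maximum(mix[observed], tiny)).sum()
                )
                loglik_trace.append(ll_val)
                alpha_trace.append(alpha)
                q_sum += q
                p_sum += p
                keep.append(sweep)

        n_keep = len(keep)
        self.Q_ = q_sum / n_keep
        self.Q_ = self.Q_ / self.Q_.sum(axis=1, keepdims=True)
        self.freqs_ = [
            (p_sum / n_keep)[:, l, : n_alleles[l]] for l in range(n_loci)
        ]
        self.loglik_trace_ = np.asarray(loglik_trace)
        self.alpha_trace_ = np.asarray(alpha_trace)
        self.ln_prob_data_ = estimate_ln_prob_data(self.loglik_trace_)
        self.individuals_ = list(genotypes.individuals)
        self.n_kept_loci_ = n_loci
        return self

    @staticmethod
    def _update_f_model(rng, p, p_anc, f_drift, n_alleles) -> None:
        """Metropolis updates of ancestral frequencies and per-cluster drift."""
        k, n_loci, _ = p.shape
        tiny = 1e-9

        def dirichlet_logpdf(x, conc):
            return (
                gammaln(conc.sum()) - gammaln(conc).sum()
                + ((conc - 1.0) * np.log(np.maximum(x, tiny))).sum()
            )

        for l in range(n_loci):
            j = n_alleles[l]
            if j < 2:
                continue
            cur = p_anc[l, :j]
            prop = np.clip(cur + rng.normal(0.0, 0.05, size=j), tiny, None)
            prop = prop / prop.sum()
            logr = 0.0
            for kk in range(k):
                f = np.clip(f_drift[kk], 1e-4, 1 - 1e-4)
                scale = (1.0 - f) / f
                logr += dirichlet_logpdf(p[kk, l, :j], prop * scale)
                logr -= dirichlet_logpdf(p[kk, l, :j], cur * scale)
            if np.log(rng.random()) < logr:
                p_anc[l, :j] = prop
        for kk in range(k):
            cur_f = f_drift[kk]
            prop_f = cur_f + rng.normal(0.0, 0.05)
            if not 1e-4 < prop_f < 1 - 1e-4:
                continue
            logr = 0.0
            for l in range(n_loci):
                j = n_alleles[l]
                if j < 2:
                    continue
                logr += dirichlet_logpdf(
                    p[kk, l, :j], p_anc[l, :j] * (1 - prop_f) / prop_f
                )
                logr -= dirichlet_logpdf(
                    p[kk, l, :j], p_anc[l, :j] * (1 - cur_f) / cur_f
                )
            if np.log(rng.random()) < logr:
                f_drift[kk] = prop_f

    def result(self, replicate: int = 0) -> ClusterResult:
        return ClusterResult(
            k=self.n_clusters,
            replicate=replicate,
            q=self.Q_,
            freqs=self.freqs_,
            loglik_trace=self.loglik_trace_,
            ln_prob_data=self.ln_prob_data_,
            alpha_trace=self.alpha_trace_,
            seed=self.random_state,
            individuals=self.individuals_,
        )


def fit_admixture(
    genotypes: GenotypeMatrix,
    k: int,
    burnin: int = 200,
    n_iter: int = 400,
    thin: int = 1,
    correlated_freqs: bool = True,
    seed: int = 0,
    replicate: int = 0,
) -> ClusterResult:
    """Fit one admixture model; thin functional wrapper over
    :class:`AdmixtureModel`."""
    model = AdmixtureModel(
        n_clusters=k, burnin=burnin, n_iter=n_iter, thin=thin,
        correlated_freqs=correlated_freqs, random_state=seed,
    )
    model.fit(genotypes)
    return model.result(replicate)


# ---------------------------------------------------------------------------
# K selection
# ---------------------------------------------------------------------------


def estimate_ln_prob_data(trace: np.ndarray) -> float:
    """ln Pr(X|K) from a post-burnin log-likelihood trace: mean - var/2
    (sample variance, n-1 denominator)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if trace.size == 1:
        return float(trace[0])
    var = float(np.var(trace, ddof=1))
    if not np.isfinite(var):
        raise ValueError("non-finite trace variance")
    return float(trace.mean() - var / 2.0)


def posterior_prob_k(ln_probs: dict[int, float]) -> dict[int, float]:
    """PP(K) under a uniform prior: stabilized softmax over ln Pr(X|K)."""
    if not ln_probs:
        raise ValueError("need at least one K")
    ks = sorted(ln_probs)
    vals = np.array([ln_probs[k] for k in ks], dtype=float)
    vals -= vals.max()
    w = np.exp(vals)
    w /= w.sum()
    return dict(zip(ks, w.tolist()))


def delta_k(ln_prob_table: dict[int, list[float]]) -> dict[int, float]:
    """Evanno's ΔK from replicated ln Pr(X|K) values.

    ΔK(K) = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd_r(L(K)), defined
    for interior K with both neighbors present and >= 2 replicates; a zero
    across-replicate standard deviation yields inf.
    """
    ks = sorted(ln_prob_table)
    if len(ks) < 3:
        raise ValueError("ΔK needs >= 3 consecutive K values")
    out: dict[int, float] = {}
    for idx in range(1, len(ks) - 1):
        k = ks[idx]
        if ks[idx - 1] != k - 1 or ks[idx + 1] != k + 1:
            continue
        reps = min(
            len(ln_prob_table[k - 1]), len(ln_prob_table[k]),
            len(ln_prob_table[k + 1]),
        )
        if reps < 2:
            raise ValueError(f"ΔK at K={k} needs >= 2 replicates")
        lm = np.array(ln_prob_table[k - 1][:reps])
        l0 = np.array(ln_prob_table[k][:reps])
        lp = np.array(ln_prob_table[k + 1][:reps])
        second = np.abs(lp - 2 * l0 + lm).mean()
        sd = float(np.std(l0, ddof=1))
        out[k] = float(second / sd) if sd > 0 else float("inf")
    return out


@dataclass
class KSelection:
    """Model-selection summary over a swept K range."""

    mean_ln_prob: dict[int, float]
    pp: dict[int, float]
    delta_k: dict[int, float]

    @property
    def best_k_pp(self) -> int:
        return max(self.pp, key=lambda k: self.pp[k])

    @property
    def best_k_delta(self) -> int | None:
        if not self.delta_k:
            return None
        return max(self.delta_k, key=lambda k: self.delta_k[k])


def select_k(ln_prob_table: dict[int, list[float]]) -> KSelection:
    mean_ln = {k: float(np.mean(v)) for k, v in ln_prob_table.items()}
    pp = posterior_prob_k(mean_ln)
    try:
        dk = delta_k(ln_prob_table)
    except ValueError:
        dk = {}
    return KSelection(mean_ln, pp, dk)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


def postprocess_memberships(q: np.ndarray, floor: float = 0.05) -> np.ndarray:
    """Zero sub-floor membership coefficients and renormalize each row.

    Coefficients below ``floor`` are disregarded and their mass assigned
    proportionally to the remaining clusters.  A row entirely below the
    floor is returned unchanged.
    """
    if not 0.0 <= floor < 1.0:
        raise ValueError("floor must lie in [0, 1)")
    q = np.asarray(q, dtype=float)
    out = q.copy()
    for i in range(q.shape[0]):
        mask = q[i] >= floor
        if not mask.any():
            continue
        row = np.where(mask, q[i], 0.0)
        out[i] = row / row.sum()
    return out


def align_cluster_labels(
    results: list[np.ndarray], reference: int = 0
) -> list[np.ndarray]:
    """Repair label switching across replicate Q matrices at the same K.

    Greedy maximum-correlation matching of columns to the reference
    replicate; deterministic given input order.  Returns column-permuted
    copies (the reference is returned as-is).
    """
    if len(results) < 2:
        return [np.asarray(r) for r in results]
    ref = np.asarray(results[reference], dtype=float)
    k = ref.shape[1]
    out: list[np.ndarray] = []
    for r, q in enumerate(results):
        q = np.asarray(q, dtype=float)
        if r == reference:
            out.append(q)
            continue
        if q.shape != ref.shape:
            raise ValueError("replicates must share Q shape")
        corr = np.zeros((k, k))
        for a in range(k):
            for b in range(k):
                sa, sb = np.std(ref[:, a]), np.std(q[:, b])
                if sa == 0 or sb == 0:
                    corr[a, b] = -np.inf if a != b else 0.0
                else:
                    corr[a, b] = np.corrcoef(ref[:, a], q[:, b])[0, 1]
        perm = np.full(k, -1)
        used: set[int] = set()
        for a, b in sorted(
            ((a, b) for a in range(k) for b in range(k)),
            key=lambda ab: -corr[ab[0], ab[1]],
        ):
            if perm[a] == -1 and b not in used:
                perm[a] = b
                used.add(b)
        out.append(q[:, perm])
    return out
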