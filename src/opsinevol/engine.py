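"""Likelihood computation and ML fitting of codon substitution models.

The substitution process is the Goldman-Yang style codon model: a
61-state continuous-time Markov chain in which only single-nucleotide
changes have nonzero rate,

    q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous],

rescaled so one unit of branch length is one expected codon
substitution under the stationary distribution pi.  Branch models give
each predefined branch class its own omega; site models mix omega
classes across columns; the branch-site "Model A" lets a site class be
positively selected on designated foreground branches only.

Likelihoods are computed by Felsenstein pruning over compressed column
patterns, with per-branch transition matrices obtained from a single
symmetric eigendecomposition per distinct omega (the chain is
reversible).  Fitting is bounded quasi-Newton (L-BFGS-B) with seeded
multi-starts; mixture proportions are optimized through stick-breaking
coordinates so box bounds suffice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.stats
from scipy.special import logsumexp

from .codons import (
    N_CODONS,
    NEIGHBOR_I,
    NEIGHBOR_J,
    NEIGHBOR_SYNONYMOUS,
    NEIGHBOR_TRANSITION,
    SENSE_CODONS,
)
from .io import BranchPartition, CodonAlignment, LabeledTree

log = logging.getLogger(__name__)

N_BETA_CATEGORIES = 10  # M7/M8 discretization (equal-probability, median rates)


# ---------------------------------------------------------------------------
# frequencies and rate matrices
# ---------------------------------------------------------------------------

def estimate_codon_frequencies(
    aln: CodonAlignment, method: str = "F3x4", epsilon: float = 0.5
) -> np.ndarray:
    """Equilibrium codon frequencies from the data.

    F3x4 builds frequencies from position-specific nucleotide counts,
    renormalized over the 61 sense codons; F61 uses observed codon
    proportions with pseudocount ``epsilon``; uniform gives 1/61.
    Only unambiguously observed codons are counted.
    """
    if aln.n_sites == 0 or aln.n_taxa == 0:
        raise ValueError("empty alignment")
    if method == "uniform":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    if method == "F61":
        counts = np.full(N_CODONS, epsilon)
        for row in aln.cells:
            for cell in row:
                if len(cell) == 1:
                    counts[next(iter(cell))] += 1
        return counts / counts.sum()
    if method == "F3x4":
        nt_index = {"A": 0, "C": 1, "G": 2, "T": 3}
        counts = np.full((3, 4), epsilon)
        for row in aln.cells:
            for cell in row:
                if len(cell) == 1:
                    codon = SENSE_CODONS[next(iter(cell))]
                    for pos, nt in enumerate(codon):
                        counts[pos, nt_index[nt]] += 1
        freqs = counts / counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                freqs[0, nt_index[c[0]]] * freqs[1, nt_index[c[1]]] * freqs[2, nt_index[c[2]]]
                for c in SENSE_CODONS
            ]
        )
        return pi / pi.sum()
    raise ValueError(f"unknown frequency method {method!r}")


def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """61x61 codon rate generator, rescaled to one expected substitution
    per codon per unit time under ``pi``."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi < 0) or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("pi must be a 61-simplex")
    if kappa < 0 or omega < 0:
        raise ValueError("kappa and omega must be nonnegative")
    rates = pi[NEIGHBOR_J] * np.where(NEIGHBOR_TRANSITION, kappa, 1.0)
    rates = rates * np.where(NEIGHBOR_SYNONYMOUS, 1.0, omega)
    Q = np.zeros((N_CODONS, N_CODONS))
    Q[NEIGHBOR_I, NEIGHBOR_J] = rates
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    if scale > 0:
        Q /= scale
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, t=0 gives the identity."""
    if not np.isfinite(t) or t < 0:
        raise ValueError(f"branch length must be finite and nonnegative, got {t}")
    return scipy.linalg.expm(Q * t)


class _Eigen:
    """Symmetric eigendecomposition of a reversible generator, giving
    cheap P(t) for many branch lengths."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.clip(np.asarray(pi, float), 1e-300, None)
        sq = np.sqrt(pi)
        B = (Q * sq[:, None]) / sq[None, :]
        B = 0.5 * (B + B.T)
        w, V = scipy.linalg.eigh(B)
        self.w = w
        self.left = V / sq[:, None] * 1.0  # D^{-1/2} V
        self.right = (V * sq[:, None]).T  # V^T D^{1/2}

    def P(self, t: float) -> np.ndarray:
        M = (self.left * np.exp(self.w * t)) @ self.right
        np.clip(M, 0.0, None, out=M)
        return M


# ---------------------------------------------------------------------------
# alignment patterns and pruning
# ---------------------------------------------------------------------------

@dataclass
class _Patterns:
    tip_masks: np.ndarray  # (n_taxa_in_tree, n_patterns, 61) float
    counts: np.ndarray  # (n_patterns,)
    col_to_pattern: np.ndarray  # (n_sites,)
    taxa: list  # tree-ordered taxa


def compress_patterns(aln: CodonAlignment, tree: LabeledTree) -> _Patterns:
    order = [t for t in tree.taxa]
    missing = [t for t in order if t not in aln.taxa]
    if missing:
        raise ValueError(f"tree taxa absent from alignment: {missing}")
    rows = [aln.cells[aln.taxa.index(t)] for t in order]
    seen: dict = {}
    col_to_pattern = np.zeros(aln.n_sites, dtype=np.intp)
    patterns = []
    counts = []
    for j in range(aln.n_sites):
        key = tuple(rows[i][j] for i in range(len(order)))
        if key in seen:
            k = seen[key]
            counts[k] += 1
        else:
            k = seen[key] = len(patterns)
            patterns.append(key)
            counts.append(1)
        col_to_pattern[j] = k
    masks = np.zeros((len(order), len(patterns), N_CODONS))
    for k, key in enumerate(patterns):
        for i, cell in enumerate(key):
            masks[i, k, list(cell)] = 1.0
    return _Patterns(
        tip_masks=masks,
        counts=np.asarray(counts, dtype=float),
        col_to_pattern=col_to_pattern,
        taxa=order,
    )


def _pattern_loglikes(
    patterns: _Patterns,
    tree: LabeledTree,
    branch_lengths: np.ndarray,
    kappa: float,
    pi: np.ndarray,
    omega_by_branch: np.ndarray,
    eig_cache: dict,
    p_cache: dict,
) -> np.ndarray:
    """Per-pattern log-likelihood for one site class (pruning with
    per-pattern rescaling)."""
    taxon_row = {t: i for i, t in enumerate(patterns.taxa)}
    n_pat = patterns.tip_masks.shape[1]
    partial = [None] * tree.n_nodes
    logscale = np.zeros(n_pat)
    for u in tree.postorder:
        kids = tree.children[u]
        if not kids:
            partial[u] = patterns.tip_masks[taxon_row[tree.leaf_label[u]]].T
            continue
        M = None
        for v in kids:
            b = tree.node_branch[v]
            key = (omega_by_branch[b], b)
            P = p_cache.get(key)
            if P is None:
                w = omega_by_branch[b]
                eig = eig_cache.get((kappa, w))
                if eig is None:
                    eig = eig_cache[(kappa, w)] = _Eigen(
                        build_rate_matrix(kappa, w, pi), pi
                    )
                P = p_cache[key] = eig.P(branch_lengths[b])
            msg = P @ partial[v]
            M = msg if M is None else M * msg
        if tree.leaf_label[u] is not None:
            # a leaf can carry children when the canonical root is a
            # leaf (2-taxon trees); its own observation still applies
            M = M * patterns.tip_masks[taxon_row[tree.leaf_label[u]]].T
        scale = M.max(axis=0)
        bad = scale <= 0
        if np.any(bad):
            scale = np.where(bad, 1.0, scale)
        M = M / scale
        logscale += np.log(scale)
        partial[u] = M
    site_like = pi @ partial[tree.root]
    if np.any(site_like <= 0):
        zero_pats = np.nonzero(site_like <= 0)[0]
        sites = [int(np.nonzero(patterns.col_to_pattern == k)[0][0]) + 1 for k in zero_pats]
        raise FloatingPointError(f"zero likelihood at codon site(s) {sites}")
    return np.log(site_like) + logscale


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class CodonModelSpec:
    """A fully specified codon model: kappa, pi and a list of site
    classes, each a (proportion, omega-per-branch) pair."""

    kappa: float
    pi: np.ndarray
    site_classes: list  # [(proportion, omega_by_branch array)]
    description: str = ""

    def validate(self, n_branches: int):
        props = np.array([p for p, _ in self.site_classes])
        if np.any(props < 0) or abs(props.sum() - 1) > 1e-8:
            raise ValueError("site-class proportions must form a simplex")
        for _, om in self.site_classes:
            if len(om) != n_branches or np.any(np.asarray(om) < 0):
                raise ValueError("invalid per-branch omega vector")


def log_likelihood(aln: CodonAlignment, tree: LabeledTree, spec: CodonModelSpec) -> float:
    """Mixture log-likelihood of the alignment under ``spec``."""
    spec.validate(tree.n_branches)
    patterns = compress_patterns(aln, tree)
    return _mixture_loglike(
        patterns, tree, tree.branch_lengths, spec.kappa, spec.pi, spec.site_classes
    )


def _mixture_loglike(patterns, tree, bl, kappa, pi, site_classes) -> float:
    eig_cache: dict = {}
    p_cache: dict = {}
    lls = []
    logp = []
    for prop, omega_by_branch in site_classes:
        if prop <= 0:
            continue
        lls.append(
            _pattern_loglikes(
                patterns, tree, bl, kappa, pi, np.asarray(omega_by_branch), eig_cache, p_cache
            )
        )
        logp.append(np.log(prop))
    site_ll = logsumexp(np.asarray(lls) + np.asarray(logp)[:, None], axis=0)
    return float(np.dot(patterns.counts, site_ll))


# ---------------------------------------------------------------------------
# model templates
# ---------------------------------------------------------------------------

BRANCH_TEMPLATES = ("1w", "2w", "3w", "4w", "4w-activity", "free", "M0")
SITE_TEMPLATES = ("M0", "M1a", "M2a", "M3", "M7", "M8")
BRANCH_SITE_TEMPLATES = ("ModelA", "ModelA-null")
ALL_TEMPLATES = tuple(dict.fromkeys(BRANCH_TEMPLATES + SITE_TEMPLATES + BRANCH_SITE_TEMPLATES))

_WMIN, _WMAX = 1e-4, 99.0
_SMIN = 1e-6  # stick-breaking bounds: must admit (near-)degenerate mixtures
           # so nested models stay representable (e.g. M7 inside M8)


def beta_category_rates(p: float, q: float, k: int = N_BETA_CATEGORIES) -> np.ndarray:
    """Medians of k equal-probability categories of Beta(p, q)."""
    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    return scipy.stats.beta.ppf(quantiles, p, q)


def _uniform_omega(n_branches, w):
    return np.full(n_branches, float(w))


class _Template:
    """Parameter layout and site-class construction for one model family."""

    def __init__(self, name: str, partition: BranchPartition | None, tree: LabeledTree):
        self.name = name
        self.tree = tree
        self.partition = partition
        nb = tree.n_branches
        if name in ("1w", "M0"):
            self.kind = "branch"
            self.class_names = ["omega"]
            self.class_of_branch = np.zeros(nb, dtype=np.intp)
        elif name in ("2w", "3w", "4w", "4w-activity", "free"):
            if partition is None:
                raise ValueError(f"model {name} requires a branch partition")
            self.kind = "branch"
            present = sorted({partition.assignment[b] for b in range(nb)})
            self.class_names = [f"omega_{partition.classes[k]}" for k in present]
            remap = {k: i for i, k in enumerate(present)}
            self.class_of_branch = np.array(
                [remap[partition.assignment[b]] for b in range(nb)], dtype=np.intp
            )
        elif name in SITE_TEMPLATES or name in BRANCH_SITE_TEMPLATES:
            self.kind = "site" if name in SITE_TEMPLATES else "branch-site"
            if self.kind == "branch-site":
                if partition is None or not partition.foreground:
                    raise ValueError(f"model {name} requires a partition with foreground branches")
                self.fg_mask = np.array(
                    [b in partition.foreground for b in range(nb)], dtype=bool
                )
        else:
            raise ValueError(f"unknown model template {name!r}")

    # parameter blocks: (name, init, lower, upper)
    def param_blocks(self):
        n = self.name
        blocks = [("kappa", 2.0, 0.05, _WMAX)]
        if self.kind == "branch":
            blocks += [(c, 0.4, _WMIN, _WMAX) for c in self.class_names]
        elif n == "M1a":
            blocks += [("s0", 0.7, _SMIN, 1 - _SMIN), ("omega0", 0.2, _WMIN, 1.0)]
        elif n == "M2a":
            blocks += [
                ("s0", 0.6, _SMIN, 1 - _SMIN),
                ("s1", 0.7, _SMIN, 1 - _SMIN),
                ("omega0", 0.2, _WMIN, 1.0),
                ("omega2", 2.5, 1.0, _WMAX),
            ]
        elif n == "M3":
            blocks += [
                ("s0", 0.5, _SMIN, 1 - _SMIN),
                ("s1", 0.5, _SMIN, 1 - _SMIN),
                ("omega0", 0.05, _WMIN, _WMAX),
                ("omega1", 0.4, _WMIN, _WMAX),
                ("omega2", 1.5, _WMIN, _WMAX),
            ]
        elif n == "M7":
            blocks += [("p", 0.5, 0.005, _WMAX), ("q", 1.5, 0.005, _WMAX)]
        elif n == "M8":
            blocks += [
                ("s0", 0.9, _SMIN, 1 - _SMIN),
                ("p", 0.5, 0.005, _WMAX),
                ("q", 1.5, 0.005, _WMAX),
                ("omega_s", 2.0, 1.0, _WMAX),
            ]
        elif n in BRANCH_SITE_TEMPLATES:
            blocks += [
                ("s0", 0.8, _SMIN, 1 - _SMIN),
                ("s1", 0.8, _SMIN, 1 - _SMIN),
                ("omega0", 0.2, _WMIN, 1.0),
            ]
            if n == "ModelA":
                blocks += [("omega2", 2.5, 1.0, _WMAX)]
        return blocks

    def site_classes(self, values: dict):
        nb = self.tree.n_branches
        n = self.name
        if self.kind == "branch":
            om = np.array([values[c] for c in self.class_names])[self.class_of_branch]
            return [(1.0, om)]
        if n == "M1a":
            p0 = values["s0"]
            return [
                (p0, _uniform_omega(nb, values["omega0"])),
                (1 - p0, _uniform_omega(nb, 1.0)),
            ]
        if n == "M2a":
            p0 = values["s0"]
            p1 = (1 - p0) * values["s1"]
            p2 = 1 - p0 - p1
            return [
                (p0, _uniform_omega(nb, values["omega0"])),
                (p1, _uniform_omega(nb, 1.0)),
                (p2, _uniform_omega(nb, values["omega2"])),
            ]
        if n == "M3":
            p0 = values["s0"]
            p1 = (1 - p0) * values["s1"]
            p2 = 1 - p0 - p1
            return [
                (p0, _uniform_omega(nb, values["omega0"])),
                (p1, _uniform_omega(nb, values["omega1"])),
                (p2, _uniform_omega(nb, values["omega2"])),
            ]
        if n in ("M7", "M8"):
            rates = beta_category_rates(values["p"], values["q"])
            weight = 1.0 if n == "M7" else values["s0"]
            classes = [(weight / len(rates), _uniform_omega(nb, r)) for r in rates]
            if n == "M8":
                classes.append((1 - weight, _uniform_omega(nb, values["omega_s"])))
            return classes
        # branch-site Model A / null
        s1, s2 = values["s0"], values["s1"]
        p01, frac0 = s1, s2
        p0, p1 = p01 * frac0, p01 * (1 - frac0)
        p2a, p2b = (1 - p01) * frac0, (1 - p01) * (1 - frac0)
        w0 = values["omega0"]
        w2 = values.get("omega2", 1.0)
        fg = self.fg_mask
        om0 = _uniform_omega(nb, w0)
        om1 = _uniform_omega(nb, 1.0)
        om2a = np.where(fg, w2, w0)
        om2b = np.where(fg, w2, 1.0)
        return [(p0, om0), (p1, om1), (p2a, om2a), (p2b, om2b)]

    def describe(self, values: dict) -> dict:
        """Human-facing parameter estimates (proportions, omegas)."""
        out = {"kappa": values["kappa"]}
        n = self.name
        if self.kind == "branch":
            for c in self.class_names:
                out[c] = values[c]
        elif n == "M1a":
            out.update(p0=values["s0"], p1=1 - values["s0"], omega0=values["omega0"])
        elif n in ("M2a", "M3"):
            p0 = values["s0"]
            p1 = (1 - p0) * values["s1"]
            out.update(p0=p0, p1=p1, p2=1 - p0 - p1)
            for k in ("omega0", "omega1", "omega2"):
                if k in values:
                    out[k] = values[k]
        elif n == "M7":
            out.update(p=values["p"], q=values["q"])
        elif n == "M8":
            out.update(p0=values["s0"], p=values["p"], q=values["q"], omega_s=values["omega_s"])
        else:
            s1, s2 = values["s0"], values["s1"]
            out.update(
                p0=s1 * s2,
                p1=s1 * (1 - s2),
                p2=1 - s1,
                omega0=values["omega0"],
                omega2=values.get("omega2", 1.0),
            )
        return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """A maximized codon-model fit."""

    model: str
    lnl: float
    K: int
    estimates: dict  # human-facing parameter estimates
    branch_lengths: np.ndarray
    site_class_summary: list  # [(proportion, omega description)]
    convergence: dict
    kappa: float = 0.0
    pi: np.ndarray | None = None
    _template: object = field(default=None, repr=False)
    _values: dict = field(default_factory=dict, repr=False)
    tree: LabeledTree | None = field(default=None, repr=False)

    def site_classes(self):
        return self._template.site_classes(self._values)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "lnL": self.lnl,
            "K": self.K,
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "branch_lengths": [float(x) for x in self.branch_lengths],
            "convergence": self.convergence,
        }


def fit_model(
    aln: CodonAlignment,
    tree: LabeledTree,
    template: str,
    partition: BranchPartition | None = None,
    pi: np.ndarray | None = None,
    frequency_model: str = "F3x4",
    optimize_branch_lengths: bool = True,
    n_starts: int = 3,
    seed: int = 0,
    init: dict | None = None,
    max_iter: int = 1000,
) -> FitResult:
    """Maximum-likelihood fit of one codon model template.

    ``init`` warm-starts named parameters (and ``branch_lengths``);
    multi-start initial points beyond the first are jittered with a
    generator seeded by ``seed``, so fits are deterministic.
    """
    if template not in ALL_TEMPLATES:
        raise ValueError(f"template must be one of {ALL_TEMPLATES}")
    tmpl = _Template(template, partition, tree)
    if pi is None:
        pi = estimate_codon_frequencies(aln, frequency_model)
    pi = np.asarray(pi, dtype=float)
    patterns = compress_patterns(aln, tree)

    blocks = tmpl.param_blocks()
    names = [b[0] for b in blocks]
    x0 = np.array([b[1] for b in blocks])
    lb = np.array([b[2] for b in blocks])
    ub = np.array([b[3] for b in blocks])
    if init:
        for i, nm in enumerate(names):
            if nm in init:
                x0[i] = np.clip(init[nm], lb[i], ub[i])
    bl0 = np.clip(tree.branch_lengths, 1e-5, 20.0)
    if init and "branch_lengths" in init:
        bl0 = np.clip(np.asarray(init["branch_lengths"], float), 1e-5, 20.0)
    if optimize_branch_lengths:
        x0 = np.concatenate([x0, bl0])
        lb = np.concatenate([lb, np.full(tree.n_branches, 1e-5)])
        ub = np.concatenate([ub, np.full(tree.n_branches, 20.0)])

    n_model = len(names)

    def unpack(x):
        values = dict(zip(names, x[:n_model]))
        bl = x[n_model:] if optimize_branch_lengths else bl0
        return values, bl

    def negloglike(x):
        values, bl = unpack(x)
        try:
            return -_mixture_loglike(
                patterns, tree, bl, values["kappa"], pi, tmpl.site_classes(values)
            )
        except FloatingPointError:
            return 1e12

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        jitter = x0 * np.exp(rng.normal(0, 0.3, size=x0.shape))
        starts.append(np.clip(jitter, lb, ub))

    best = None
    nfev = 0
    for x_init in starts:
        res = scipy.optimize.minimize(
            negloglike,
            x_init,
            method="L-BFGS-B",
            bounds=list(zip(lb, ub)),
            options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-6},
        )
        nfev += res.nfev
        if best is None or res.fun < best.fun:
            best = res

    values, bl = unpack(best.x)
    K = len(best.x)
    classes = tmpl.site_classes(values)
    summary = [(float(p), np.unique(np.round(om, 6)).tolist()) for p, om in classes]
    fitted_tree = tree.with_branch_lengths(bl) if optimize_branch_lengths else tree
    return FitResult(
        model=template,
        lnl=-float(best.fun),
        K=K,
        estimates=tmpl.describe(values),
        branch_lengths=np.asarray(bl, float).copy(),
        site_class_summary=summary,
        convergence={
            "converged": bool(best.success),
            "status": str(best.message),
            "n_starts": len(starts),
            "nfev": int(nfev),
        },
        kappa=float(values["kappa"]),
        pi=pi,
        _template=tmpl,
        _values=values,
        tree=fitted_tree,
    )
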