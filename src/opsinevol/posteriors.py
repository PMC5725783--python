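"""Empirical-Bayes posteriors for site classes of fitted mixture models.

NEB plugs the MLEs straight into Bayes' rule per column.  BEB instead
averages the per-site class posteriors over a coarse grid prior on the
mixture parameters (proportions and the omegas of the extreme classes),
weighting grid points by their likelihood given the whole alignment;
kappa and branch lengths stay at their MLEs.  BEB is available for the
positive-selection mixtures (M2a and branch-site Model A), where the
sampling error of the mixture MLEs matters most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .engine import FitResult, _Patterns, _pattern_loglikes, compress_patterns
from .io import CodonAlignment, LabeledTree

_GRID = 10  # categories per BEB grid dimension


@dataclass
class SitePosterior:
    """Per-site posterior over site classes (1-based site reporting)."""

    model: str
    method: str
    class_posteriors: np.ndarray  # (n_sites, n_classes)
    positive_class_posterior: np.ndarray  # (n_sites,)
    positive_sites_95: list
    positive_sites_99: list

    def flagged(self, threshold: float):
        return [
            int(i) + 1
            for i in np.nonzero(self.positive_class_posterior >= threshold)[0]
        ]


def _positive_mask(fit: FitResult, classes) -> np.ndarray:
    """Site classes whose omega exceeds 1 anywhere (foreground included)."""
    return np.array([np.any(np.asarray(om) > 1.0 + 1e-9) for _, om in classes])


def _class_loglike_matrix(fit, patterns, tree, classes) -> np.ndarray:
    eig_cache: dict = {}
    p_cache: dict = {}
    rows = []
    for _, om in classes:
        rows.append(
            _pattern_loglikes(
                patterns,
                tree,
                fit.branch_lengths,
                fit.kappa,
                fit.pi,
                np.asarray(om),
                eig_cache,
                p_cache,
            )
        )
    return np.asarray(rows)  # (n_classes, n_patterns)


def site_posteriors(
    fit: FitResult,
    aln: CodonAlignment,
    tree: LabeledTree,
    method: str = "NEB",
) -> SitePosterior:
    """Posterior probability of each site class at every codon column.

    Requires a fitted model with at least two site classes.  The
    "positive" class posterior aggregates all classes with omega > 1;
    sites exceeding 0.95 / 0.99 are reported (1-based columns).
    """
    classes = fit.site_classes()
    if len(classes) < 2:
        raise ValueError("site posteriors need a model with >= 2 site classes")
    tree = fit.tree if fit.tree is not None else tree
    patterns = compress_patterns(aln, tree)
    if method == "NEB":
        post_pat = _neb(fit, patterns, tree, classes)
    elif method == "BEB":
        post_pat = _beb(fit, patterns, tree)
    else:
        raise ValueError("method must be NEB or BEB")
    post = post_pat[:, patterns.col_to_pattern].T  # (n_sites, n_classes)
    pos_mask = _positive_mask(fit, classes)
    pos = post[:, pos_mask].sum(axis=1) if pos_mask.any() else np.zeros(post.shape[0])
    sp = SitePosterior(
        model=fit.model,
        method=method,
        class_posteriors=post,
        positive_class_posterior=pos,
        positive_sites_95=[],
        positive_sites_99=[],
    )
    sp.positive_sites_95 = sp.flagged(0.95)
    sp.positive_sites_99 = sp.flagged(0.99)
    return sp


def _neb(fit, patterns, tree, classes) -> np.ndarray:
    ll = _class_loglike_matrix(fit, patterns, tree, classes)
    logp = np.log(np.clip([p for p, _ in classes], 1e-300, None))[:, None]
    joint = logp + ll
    return np.exp(joint - logsumexp(joint, axis=0, keepdims=True))


def _midpoints(lo, hi, k=_GRID):
    edges = np.linspace(lo, hi, k + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def _beb(fit, patterns, tree) -> np.ndarray:
    if fit.model == "M2a":
        return _beb_m2a(fit, patterns, tree)
    if fit.model in ("ModelA", "ModelA-null"):
        return _beb_model_a(fit, patterns, tree)
    raise ValueError(f"BEB implemented for M2a and Model A, not {fit.model}")


def _cond_loglikes(fit, patterns, tree, omega_vectors) -> np.ndarray:
    eig_cache: dict = {}
    p_cache: dict = {}
    return np.asarray(
        [
            _pattern_loglikes(
                patterns, tree, fit.branch_lengths, fit.kappa, fit.pi, om, eig_cache, p_cache
            )
            for om in omega_vectors
        ]
    )


def _grid_average(log_f_by_class, counts):
    """Average class posteriors over grid points weighted by the data.

    ``log_f_by_class``: iterable over grid points of (props, log f_k(x_h))
    with shapes (n_classes,), (n_classes, n_patterns).
    """
    entries = list(log_f_by_class)
    n_classes, n_pat = entries[0][1].shape
    log_site = np.empty((len(entries), n_pat))
    post_num = np.empty((len(entries), n_classes, n_pat))
    for g, (props, logf) in enumerate(entries):
        lp = np.log(np.clip(props, 1e-300, None))[:, None]
        joint = lp + logf
        ls = logsumexp(joint, axis=0)
        log_site[g] = ls
        post_num[g] = np.exp(joint - ls)
    log_w = log_site @ counts  # log P(data | grid point), uniform prior
    w = np.exp(log_w - logsumexp(log_w))
    return np.tensordot(w, post_num, axes=1)  # (n_classes, n_patterns)


def _beb_m2a(fit, patterns, tree) -> np.ndarray:
    nb = tree.n_branches
    w0_grid = _midpoints(0.0, 1.0)
    w2_grid = _midpoints(1.0, 11.0)
    s_grid = _midpoints(0.0, 1.0)
    omegas = list(w0_grid) + [1.0] + list(w2_grid)
    ll = _cond_loglikes(fit, patterns, tree, [np.full(nb, w) for w in omegas])
    f_w0 = {w: ll[i] for i, w in enumerate(w0_grid)}
    f_one = ll[len(w0_grid)]
    f_w2 = {w: ll[len(w0_grid) + 1 + i] for i, w in enumerate(w2_grid)}

    def gridpoints():
        for s0 in s_grid:
            for s1 in s_grid:
                p0, p1 = s0, (1 - s0) * s1
                p2 = 1 - p0 - p1
                for w0 in w0_grid:
                    for w2 in w2_grid:
                        yield (
                            np.array([p0, p1, p2]),
                            np.vstack([f_w0[w0], f_one, f_w2[w2]]),
                        )

    return _grid_average(gridpoints(), patterns.counts)


def _beb_model_a(fit, patterns, tree) -> np.ndarray:
    nb = tree.n_branches
    fg = fit._template.fg_mask
    w0_grid = _midpoints(0.0, 1.0)
    w2_grid = _midpoints(1.0, 11.0)
    s_grid = _midpoints(0.0, 1.0)

    f0 = {w0: None for w0 in w0_grid}
    vectors = []
    keys = []
    for w0 in w0_grid:
        vectors.append(np.full(nb, w0))
        keys.append(("c0", w0))
    vectors.append(np.full(nb, 1.0))
    keys.append(("c1",))
    for w0 in w0_grid:
        for w2 in w2_grid:
            vectors.append(np.where(fg, w2, w0))
            keys.append(("c2a", w0, w2))
    for w2 in w2_grid:
        vectors.append(np.where(fg, w2, 1.0))
        keys.append(("c2b", w2))
    ll = _cond_loglikes(fit, patterns, tree, vectors)
    table = dict(zip(keys, ll))

    def gridpoints():
        for s0 in s_grid:
            for s1 in s_grid:
                p01, frac0 = s0, s1
                props = np.array(
                    [
                        p01 * frac0,
                        p01 * (1 - frac0),
                        (1 - p01) * frac0,
                        (1 - p01) * (1 - frac0),
                    ]
                )
                for w0 in w0_grid:
                    for w2 in w2_grid:
                        yield (
                            props,
                            np.vstack(
                                [
                                    table[("c0", w0)],
                                    table[("c1",)],
                                    table[("c2a", w0, w2)],
                                    table[("c2b", w2)],
                                ]
                            ),
                        )

    return _grid_average(gridpoints(), patterns.counts)
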