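"""Synthetic data with known truth: codon alignments evolved under
branch/site-heterogeneous omega on labeled trees, and opsin coding
sequences carrying chosen residues at canonical tuning sites on a
bovine-rhodopsin-like backbone.

Simulation semantics for branch-site mixtures: a site's class is drawn
once (at the root) and is global; the class's "foreground" omega
applies only on foreground branches, the background omega elsewhere.
All randomness flows from a single master seed through named
per-stream child seeds, which are recorded in the truth record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine
from .codons import CODON_AA, CODON_INDEX, N_CODONS, SENSE_CODONS, codon_cell
from .io import BranchPartition, CodonAlignment, LabeledTree, iupac_codon_for
from .tuning import BOVINE_RHODOPSIN, CANONICAL_SITES, default_rules, predict_lambda_max


def _child_seed(seed: int, stream: str) -> int:
    import zlib

    h = zlib.crc32(stream.encode())  # stable across processes
    return int(np.random.SeedSequence([seed, h]).generate_state(1)[0] % (2**31))


@dataclass
class SimulationSpec:
    """Generative settings for one codon alignment."""

    tree: LabeledTree
    partition: BranchPartition
    omega_by_class: dict  # class name -> true omega
    kappa: float = 2.0
    pi: np.ndarray | None = None  # default uniform
    site_mixture: list | None = None  # [(prop, {"background": w, "foreground": w}), ...]
    L: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.pi is None:
            self.pi = np.full(N_CODONS, 1.0 / N_CODONS)
        for name in self.omega_by_class:
            if name not in self.partition.classes:
                raise ValueError(f"omega given for unknown class {name!r}")


def _branch_omegas(spec: SimulationSpec) -> np.ndarray:
    om = np.empty(spec.tree.n_branches)
    for b in range(spec.tree.n_branches):
        cls = spec.partition.classes[spec.partition.assignment[b]]
        om[b] = spec.omega_by_class[cls]
    return om


def simulate_alignment(spec: SimulationSpec):
    """Evolve an alignment along the tree; returns (alignment, truth).

    Root codons are drawn from pi; each branch evolves its sites with
    the transition matrix of its class omega (site-mixture foreground
    omegas override on foreground branches).  The truth record carries
    the per-site class labels and all generative parameters.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    L = spec.L
    pi = spec.pi

    if spec.site_mixture:
        props = np.array([p for p, _ in spec.site_mixture])
        if abs(props.sum() - 1) > 1e-8:
            raise ValueError("site mixture proportions must sum to 1")
        site_class = rng.choice(len(props), size=L, p=props)
    else:
        site_class = np.zeros(L, dtype=int)

    base_omega = _branch_omegas(spec)
    fg = np.array(
        [b in spec.partition.foreground for b in range(tree.n_branches)], dtype=bool
    )

    # per (site-class, branch) omega
    def omega_for(k: int, b: int) -> float:
        if not spec.site_mixture:
            return base_omega[b]
        entry = spec.site_mixture[k][1]
        if isinstance(entry, dict):
            return float(entry["foreground"] if fg[b] else entry["background"])
        return float(entry)

    eigs: dict = {}

    def P_matrix(w: float, t: float) -> np.ndarray:
        if w not in eigs:
            eigs[w] = engine._Eigen(engine.build_rate_matrix(spec.kappa, w, pi), pi)
        return eigs[w].P(t)

    states = {tree.root: rng.choice(N_CODONS, size=L, p=pi)}
    for u in reversed(tree.postorder):
        for v in tree.children[u]:
            b = tree.node_branch[v]
            t = tree.branch_lengths[b]
            child = np.empty(L, dtype=int)
            for k in np.unique(site_class):
                P = P_matrix(omega_for(int(k), b), t)
                cum = np.cumsum(P, axis=1)
                idx = np.nonzero(site_class == k)[0]
                u01 = rng.random(idx.size)
                parent_states = states[u][idx]
                child[idx] = np.array(
                    [np.searchsorted(cum[s], r) for s, r in zip(parent_states, u01)]
                )
            states[v] = np.clip(child, 0, N_CODONS - 1)

    taxa, cells = [], []
    for iu in range(tree.n_nodes):
        if tree.leaf_label[iu] is not None:
            taxa.append(tree.leaf_label[iu])
            cells.append([frozenset([int(s)]) for s in states[iu]])
    order = sorted(range(len(taxa)), key=lambda i: taxa[i])
    aln = CodonAlignment(
        taxa=[taxa[i] for i in order],
        cells=[cells[i] for i in order],
        nt_length=3 * L,
    )
    truth = {
        "seed": spec.seed,
        "kappa": spec.kappa,
        "omega_by_class": dict(spec.omega_by_class),
        "site_class": site_class.tolist(),
        "site_mixture": spec.site_mixture,
        "L": L,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# opsin fixtures
# ---------------------------------------------------------------------------

_PREFERRED_CODON: dict = {}


def _codon_for_aa(aa: str, pi: np.ndarray | None = None) -> str:
    """Highest-pi (default: alphabetically first) sense codon for an
    amino acid."""
    if pi is None:
        if not _PREFERRED_CODON:
            for c, a in zip(SENSE_CODONS, CODON_AA):
                _PREFERRED_CODON.setdefault(a, c)
        return _PREFERRED_CODON[aa]
    best, best_p = None, -1.0
    for i, (c, a) in enumerate(zip(SENSE_CODONS, CODON_AA)):
        if a == aa and pi[i] > best_p:
            best, best_p = c, pi[i]
    if best is None:
        raise ValueError(f"no codon for amino acid {aa!r}")
    return best


def _het_codon(aas: frozenset) -> str:
    """Single IUPAC codon whose sense expansion translates exactly to
    the requested residue set."""
    from itertools import product

    symbols = "ACGTRYSWKMBDHVN"
    target = frozenset(aas)
    best = None
    for t in product(symbols, repeat=3):
        codon = "".join(t)
        try:
            cell = codon_cell(codon)
        except ValueError:
            continue
        if frozenset(CODON_AA[i] for i in cell) == target:
            if best is None or len(cell) < len(codon_cell(best)):
                best = codon
    if best is None:
        raise ValueError(f"residue set {sorted(target)} not encodable by one IUPAC codon")
    return best


@dataclass
class FixtureSpec:
    """A synthetic opsin coding sequence with known tuning-site truth."""

    opsin_class: str
    residues: dict = field(default_factory=dict)  # site -> aa or set of aa
    n_terminal_extension: str = ""
    deletions: tuple = ()  # bovine positions deleted from the query
    seed: int = 0

    def __post_init__(self):
        for site, aa in self.residues.items():
            aas = {aa} if isinstance(aa, str) else set(aa)
            for a in aas:
                if a not in "ACDEFGHIKLMNPQRSTVWY":
                    raise ValueError(f"illegal residue {a!r} at site {site}")


def make_opsin_fixture(spec: FixtureSpec):
    """Build a coding DNA fixture and its truth record.

    The protein is the bovine-rhodopsin backbone with the opsin class's
    base residues imposed at its canonical sites, then the requested
    residue (sets) applied; heterozygous sites are emitted as single
    IUPAC codons.  Truth carries the expected tuning profile and the
    lambda_max predictions of the default rule set.
    """
    rules = default_rules(spec.opsin_class)
    protein = list(BOVINE_RHODOPSIN)
    site_residues: dict = {}
    for site in CANONICAL_SITES[spec.opsin_class]:
        site_residues[site] = frozenset(protein[site - 1])
    for site, aa in rules.base_profile.items():
        protein[site - 1] = aa
        site_residues[site] = frozenset(aa)
    het: dict = {}
    for site, aa in spec.residues.items():
        aas = frozenset({aa} if isinstance(aa, str) else aa)
        site_residues[site] = aas
        if len(aas) == 1:
            protein[site - 1] = next(iter(aas))
        else:
            protein[site - 1] = None  # placeholder, emitted as IUPAC codon
            het[site] = aas

    codons = []
    for pos0, aa in enumerate(protein):
        site = pos0 + 1
        if site in spec.deletions:
            continue
        if aa is None:
            codons.append(_het_codon(het[site]))
        else:
            codons.append(_codon_for_aa(aa))
    ext = "".join(_codon_for_aa(a) for a in spec.n_terminal_extension.upper())
    dna = ext + "".join(codons)

    truth_profile = {
        site: (None if site in spec.deletions else site_residues[site])
        for site in CANONICAL_SITES[spec.opsin_class]
    }
    from .tuning import TuningSiteProfile

    profile = TuningSiteProfile(opsin_class=spec.opsin_class, residues=truth_profile)
    prediction = predict_lambda_max(profile, rules)
    truth = {
        "opsin_class": spec.opsin_class,
        "profile": {s: (sorted(r) if r else None) for s, r in truth_profile.items()},
        "lambda_max": [e.lambda_nm for e in prediction.entries],
        "labels": [e.label for e in prediction.entries],
        "provenance": [e.provenance for e in prediction.entries],
    }
    return dna, truth


def translate_fixture(dna: str):
    """Codon cells -> per-position amino-acid sets (propagates IUPAC)."""
    if len(dna) % 3:
        raise ValueError("fixture length not divisible by 3")
    cells = [codon_cell(dna[i : i + 3]) for i in range(0, len(dna), 3)]
    return [frozenset(CODON_AA[i] for i in c) for c in cells]


# ---------------------------------------------------------------------------
# recovery / calibration experiments
# ---------------------------------------------------------------------------

def recovery_experiment(
    spec: SimulationSpec,
    fit_template: str,
    replicates: int,
    seed: int = 0,
    n_starts: int = 1,
    compare_with: str | None = None,
    alpha: float = 0.05,
    df: int = 1,
):
    """Simulate under ``spec`` and refit ``fit_template`` per replicate.

    Returns a report dict with per-replicate estimates and, when
    ``compare_with`` names a nested template, the LRT rejection rate of
    ``fit_template`` against it at level ``alpha``.
    """
    from .selection import lrt

    if replicates < 1:
        raise ValueError("replicate count must be >= 1")
    estimates = []
    rejections = 0
    rep_seeds = []
    for r in range(replicates):
        s = _child_seed(seed, f"rep{r}")
        rep_seeds.append(s)
        rep_spec = SimulationSpec(
            tree=spec.tree,
            partition=spec.partition,
            omega_by_class=spec.omega_by_class,
            kappa=spec.kappa,
            pi=spec.pi,
            site_mixture=spec.site_mixture,
            L=spec.L,
            seed=s,
        )
        aln, _ = simulate_alignment(rep_spec)
        init_rich = None
        fit0 = None
        if compare_with:
            # fit the nested model first and warm-start the rich one from
            # it, so the nesting inequality holds per replicate
            fit0 = engine.fit_model(
                aln,
                spec.tree,
                compare_with,
                partition=spec.partition,
                n_starts=n_starts,
                seed=s,
            )
            rich_names = [
                b[0]
                for b in engine._Template(fit_template, spec.partition, spec.tree).param_blocks()
            ]
            base_omega = fit0.estimates.get("omega", 0.4)
            init_rich = {"kappa": fit0.kappa, "branch_lengths": fit0.branch_lengths}
            for nm in rich_names:
                if nm.startswith("omega"):
                    init_rich[nm] = fit0.estimates.get(nm, base_omega)
        fit = engine.fit_model(
            aln,
            spec.tree,
            fit_template,
            partition=spec.partition,
            n_starts=n_starts,
            seed=s,
            init=init_rich,
        )
        estimates.append(fit.estimates)
        if compare_with:
            res = lrt(fit0.lnl, fit.lnl, df)
            if res.p < alpha:
                rejections += 1
    report = {
        "template": fit_template,
        "replicates": replicates,
        "estimates": estimates,
        "replicate_seeds": rep_seeds,
        "truth": dict(spec.omega_by_class),
    }
    for key in estimates[0]:
        vals = np.array([e[key] for e in estimates])
        report.setdefault("summary", {})[key] = {
            "median": float(np.median(vals)),
            "mean": float(vals.mean()),
        }
    if compare_with:
        report["rejection_rate"] = rejections / replicates
        report["alpha"] = alpha
    return report
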