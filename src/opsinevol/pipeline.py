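"""End-to-end selection and spectral-tuning analyses from one config.

``run_selection_analysis`` fits the requested codon models on an
alignment + labeled tree (warm-starting each model from its nested
predecessor so the likelihood nesting holds), assembles the
branch/site-model comparison table and LRT list, flags the best branch
model by BIC, and computes empirical-Bayes site posteriors for the
positive-selection models whose LRTs are significant.

``run_spectral_report`` translates coding sequences, numbers them
against bovine rhodopsin, and emits a per-species table of tuning-site
residues and predicted lambda_max.

Every output file carries the config hash and seed in '#' header
lines, and identical configs reproduce outputs byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import engine, posteriors, selection
from .io import (
    foreground_from_class,
    label_branches,
    read_activity_table,
    read_alignment,
    read_tree,
)
from .codons import cell_amino_acids
from .tuning import align_to_reference, extract_profile, predict_lambda_max, rules_from_text, default_rules

log = logging.getLogger(__name__)

#: model fitting order and warm-start predecessors
_WARM_START = {
    "2w": "1w",
    "3w": "2w",
    "4w": "3w",
    "4w-activity": "3w",
    "free": "4w-activity",
    "M1a": "M0",
    "M2a": "M1a",
    "M3": "M0",
    "M8": "M7",
    "ModelA": "ModelA-null",
}
_ORDER = [
    "1w", "2w", "3w", "4w", "4w-activity", "free",
    "M0", "M1a", "M2a", "M3", "M7", "M8", "ModelA-null", "ModelA",
]
_DEFAULT_COMPARISONS = [
    ("2w", "1w"),
    ("3w", "2w"),
    ("4w", "3w"),
    ("4w-activity", "3w"),
    ("free", "1w"),
    ("M3", "M0"),
    ("M2a", "M1a"),
    ("M8", "M7"),
    ("ModelA", "ModelA-null"),
]
BRANCH_MODELS = ("1w", "2w", "3w", "4w", "4w-activity", "free")


@dataclass
class RunConfig:
    """Settings for one pipeline run (see the CLI for flag names)."""

    alignment: str = ""
    tree: str = ""
    labels: str = ""
    rules: str = ""  # optional rule-table override for spectral runs
    opsin_class: str = ""
    models: list = field(default_factory=lambda: ["1w", "2w"])
    foreground_classes: list = field(default_factory=list)  # branch-site foregrounds
    bic_n: float | None = None  # default: alignment length in codons
    site_method: str = "NEB"
    cleandata: bool = False
    frequency_model: str = "F3x4"
    internal_labeling: str = "clade"
    n_starts: int = 1
    seed: int = 0
    out_dir: str = "opsinevol_out"
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        # out_dir is excluded: the same analysis written elsewhere must
        # byte-reproduce, including this hash in the headers
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(fields, sort_keys=True).encode()
        ).hexdigest()[:12]

    def metadata(self) -> dict:
        return {"config_hash": self.digest(), "seed": self.seed}

    def validate_paths(self, need=("alignment", "tree")):
        for key in need:
            p = getattr(self, key)
            if not p or not Path(p).exists():
                raise ValueError(f"config {key!r} missing or does not exist: {p!r}")


def _write_tsv(df: pd.DataFrame, path, metadata: dict):
    with open(path, "w") as fh:
        for k, v in metadata.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _scheme_of(model: str) -> str | None:
    return model if model in ("2w", "3w", "4w", "4w-activity", "free") else None


def _warm_init(m: str, f0, partition, tree) -> dict | None:
    """Initial point for model ``m`` at (or next to) the optimum of its
    nested predecessor fit ``f0``, mapped into ``m``'s coordinates, so
    the fitted likelihood can only move up the nesting chain."""
    if f0 is None:
        return None
    e = f0.estimates
    init = {"kappa": f0.kappa, "branch_lengths": f0.branch_lengths}
    if _scheme_of(m) or m == "1w":
        base = e.get("omega", 0.4)
        tmpl = engine._Template(m, partition, tree)
        for nm in [b[0] for b in tmpl.param_blocks()]:
            if nm.startswith("omega"):
                init[nm] = e.get(nm, base)
        return init
    if m == "M1a":  # from M0 (approximate: M0 is not nested in M1a)
        init.update(s0=0.95, omega0=min(e.get("omega", 0.3), 0.99))
    elif m == "M2a":  # from M1a: empty positive class at omega2=1
        init.update(s0=e["p0"], s1=1 - 1e-6, omega0=e["omega0"], omega2=1.0)
    elif m == "M3":  # from M0: three identical classes
        w = e.get("omega", 0.3)
        init.update(s0=1 / 3, s1=0.5, omega0=w, omega1=w, omega2=w)
    elif m == "M8":  # from M7: vanishing positive class at omega_s=1
        init.update(s0=1 - 1e-6, p=e["p"], q=e["q"], omega_s=1.0)
    elif m == "ModelA":  # from its null: omega2 at the boundary
        p01 = e["p0"] + e["p1"]
        init.update(
            s0=min(max(p01, 1e-6), 1 - 1e-6),
            s1=min(max(e["p0"] / p01 if p01 > 0 else 0.5, 1e-6), 1 - 1e-6),
            omega0=e["omega0"],
            omega2=1.0,
        )
    return init


def run_selection_analysis(config: RunConfig, write: bool = True):
    """Fit the configured models and emit comparison tables + posteriors.

    Returns (ModelComparisonTable, {model: FitResult}, {model: SitePosterior}).
    """
    config.validate_paths(("alignment", "tree"))
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    meta = config.metadata()

    stage = "read-inputs"
    try:
        aln = read_alignment(config.alignment, cleandata=config.cleandata)
        tree = read_tree(config.tree, taxa=aln.taxa, extra_leaf="prune")
        table = read_activity_table(config.labels) if config.labels else None
        models = [m for m in _ORDER if m in config.models]
        unknown = set(config.models) - set(_ORDER)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        needs_labels = [m for m in models if _scheme_of(m) or m.startswith("ModelA")]
        if needs_labels and table is None:
            raise ValueError(f"models {needs_labels} need a branch-class label table")
        if any(m.startswith("ModelA") for m in models) and not config.foreground_classes:
            raise ValueError("branch-site models need foreground_classes")

        pi = engine.estimate_codon_frequencies(aln, config.frequency_model)
        n = config.bic_n if config.bic_n else aln.n_sites

        stage = "fit-models"
        fits: dict = {}
        fit_list = []
        for m in models:
            t0 = time.time()
            partition = None
            if _scheme_of(m):
                partition = label_branches(tree, table, _scheme_of(m), config.internal_labeling)
            init = _warm_init(m, fits.get(_WARM_START.get(m)), partition, tree)
            if m.startswith("ModelA"):
                base_part = label_branches(tree, table, "1w", config.internal_labeling)
                act_part = label_branches(tree, table, "4w-activity", config.internal_labeling)
                for fg_class in config.foreground_classes:
                    fg_branches = act_part.branches_of_class(fg_class)
                    if not fg_branches:
                        raise ValueError(f"foreground class {fg_class!r} selects no branch")
                    part_fg = base_part.with_foreground(fg_branches)
                    name = f"{m}({fg_class})"
                    fit = engine.fit_model(
                        aln, tree, m, partition=part_fg, pi=pi,
                        n_starts=config.n_starts, seed=config.seed, init=init,
                    )
                    fit.model = name
                    fits[name] = fit
                    fit_list.append(fit)
                    log.info("fitted %s in %.1fs lnL=%.2f", name, time.time() - t0, fit.lnl)
                continue
            fit = engine.fit_model(
                aln, tree, m, partition=partition, pi=pi,
                n_starts=config.n_starts, seed=config.seed, init=init,
            )
            fits[m] = fit
            fit_list.append(fit)
            log.info("fitted %s in %.1fs lnL=%.2f", m, time.time() - t0, fit.lnl)

        stage = "compare-models"
        comparisons = []
        for rich, nested in _DEFAULT_COMPARISONS:
            if rich == "ModelA":
                for fg_class in config.foreground_classes:
                    r, nn = f"ModelA({fg_class})", f"ModelA-null({fg_class})"
                    if r in fits and nn in fits:
                        comparisons.append((r, nn, selection.DEFAULT_DF[("ModelA", "ModelA-null")]))
            elif rich in fits and nested in fits:
                comparisons.append((rich, nested))
        comp = selection.compare_models(fit_list, comparisons, n=n)
        branch_rows = comp.table[comp.table["model"].isin(BRANCH_MODELS)]
        best_branch = (
            str(branch_rows.loc[branch_rows["BIC"].idxmin(), "model"])
            if len(branch_rows)
            else ""
        )

        stage = "site-posteriors"
        posts: dict = {}
        sig = {r.comparison.split(" x ")[0]: r.p < config.alpha for r in comp.lrts}
        for name, fit in fits.items():
            base = name.split("(")[0]
            if base not in ("M2a", "M8", "ModelA"):
                continue
            if not sig.get(name, False):
                continue
            posts[name] = posteriors.site_posteriors(fit, aln, tree, method=config.site_method)

        if write:
            _write_tsv(comp.table, out / "model_table.tsv", {**meta, "best_branch_model": best_branch, "bic_n": n})
            _write_tsv(comp.lrt_frame(), out / "lrt.tsv", meta)
            with open(out / "fits.json", "w") as fh:
                json.dump(
                    {"metadata": meta, "best_branch_model": best_branch,
                     "fits": {m: f.to_dict() for m, f in fits.items()}},
                    fh, indent=1,
                )
            for name, sp in posts.items():
                df = pd.DataFrame(
                    {
                        "site": range(1, sp.class_posteriors.shape[0] + 1),
                        "p_positive": sp.positive_class_posterior,
                        "flag_95": [s in sp.positive_sites_95 for s in range(1, sp.class_posteriors.shape[0] + 1)],
                        "flag_99": [s in sp.positive_sites_99 for s in range(1, sp.class_posteriors.shape[0] + 1)],
                    }
                )
                safe = name.replace("(", "_").replace(")", "")
                _write_tsv(df, out / f"sites_{safe}.tsv", {**meta, "method": sp.method})
        comp.best_model = best_branch or comp.best_model
        return comp, fits, posts
    except Exception:
        log.error("selection analysis failed at stage %s", stage)
        raise


def _read_coding_fasta(path):
    """Unaligned coding sequences -> (species, codon cells); terminal
    stops are trimmed, internal stops become missing cells."""
    from Bio import SeqIO

    from .codons import FULL_SET, codon_cell

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper().replace("-", "")
        if len(s) % 3:
            raise ValueError(f"sequence {rec.id!r} length {len(s)} not divisible by 3")
        cells = []
        for j in range(0, len(s), 3):
            try:
                cells.append(codon_cell(s[j : j + 3]))
            except ValueError:
                if j == len(s) - 3:
                    continue  # trailing stop
                cells.append(FULL_SET)
        out.append((rec.id, cells))
    return out


def run_spectral_report(config: RunConfig, write: bool = True) -> pd.DataFrame:
    """Per-species tuning-site residues and lambda_max predictions."""
    config.validate_paths(("alignment",))
    if config.opsin_class not in ("LWS", "RH1", "SWS1"):
        raise ValueError("spectral analysis needs opsin_class in {LWS, RH1, SWS1}")
    if config.rules:
        with open(config.rules) as fh:
            rules = rules_from_text(fh.read())
    else:
        rules = default_rules(config.opsin_class)

    rows = []
    for species, cells in _read_coding_fasta(config.alignment):
        aa_sets = [cell_amino_acids(c) for c in cells]
        query = "".join(sorted(a)[0] if len(a) == 1 else "X" for a in aa_sets)
        try:
            smap = align_to_reference(query)
            profile = extract_profile(aa_sets, smap, config.opsin_class)
            pred = predict_lambda_max(profile, rules)
        except ValueError as err:
            raise ValueError(f"species {species!r}: {err}") from err
        row = {"species": species}
        for site in sorted(profile.residues):
            r = profile.residues[site]
            row[f"site_{site}"] = "/".join(sorted(r)) if r else "?"
        row["heterozygous"] = any(r and len(r) > 1 for r in profile.residues.values())
        row["lambda_max_nm"] = ";".join(
            "NA" if e.lambda_nm is None else f"{e.lambda_nm:g}" for e in pred.entries
        )
        row["label"] = ";".join(e.label or "-" for e in pred.entries)
        row["provenance"] = ";".join(e.provenance for e in pred.entries)
        row["flags"] = ";".join(",".join(e.flags) or "-" for e in pred.entries)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        log.warning("no sequences in %s; spectral table is empty", config.alignment)
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_tsv(df, out / f"spectral_{config.opsin_class}.tsv", config.metadata())
    return df
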