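"""Bovine-rhodopsin numbering and rule-based visual-pigment lambda-max prediction.

Visual opsins are numbered by convention against the bovine rhodopsin
protein; a handful of "spectral tuning sites" in that numbering carry
most of the variation in the pigment's wavelength of peak absorbance
(lambda_max).  This module maps a query opsin onto the reference
numbering via deterministic global alignment, extracts residues at the
canonical tuning sites of its opsin class (LWS / RH1 / SWS1), and
predicts lambda_max from literature rules: known residue *combinations*
take precedence, otherwise single-substitution shifts are summed onto
the class's long-wavelength base pigment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio import Align
from Bio.Align import substitution_matrices

#: bovine rhodopsin (348 aa), the numbering reference
BOVINE_RHODOPSIN = (
    "MNGTEGPNFYVPFSNKTGVVRSPFEAPQYYLAEPWQFSMLAAYMFLLIMLGFPINFLTLYVTVQHKKLRTPLNYILLNLAVADLFMVFGG"
    "FTTTLYTSLHGYFVFGPTGCNLEGFFATLGGEIALWSLVVLAIERYVVVCKPMSNFRFGENHAIMGVAFTWVMALACAAPPLVGWSRYIP"
    "EGMQCSCGIDYYTPHEETNNESFVIYMFVVHFIIPLIVIFFCYGQLVFTVKEAAAQQQESATTQKAEKEVTRMVIIMVIAFLICWLPYAG"
    "VAFYIFTHQGSDFGPIFMTIPAFFAKTSAVYNPVIYIMMNKQFRNCMVTTLCCGKNPLGDDEASTTVSKTETSQVAPA"
)

OPSIN_CLASSES = ("LWS", "RH1", "SWS1")

#: canonical tuning sites (bovine numbering) per opsin class
CANONICAL_SITES = {
    "LWS": (164, 181, 261, 269, 292),
    "RH1": (83, 90, 113, 118, 122, 164, 180, 261, 265, 269, 285, 292, 299),
    "SWS1": (86, 46, 49, 52, 90, 93, 97, 113, 114, 116, 118, 265),
}


@dataclass
class SiteMap:
    """Reference-position -> query-position map from a global alignment.

    Positions are 1-based; only mutually aligned (non-gap) columns
    appear, so both coordinates are strictly increasing.
    """

    pairs: list  # [(ref_pos, query_pos), ...]
    score: float

    def __post_init__(self):
        self._ref_to_query = dict(self.pairs)

    def query_position(self, ref_pos: int):
        """1-based query position aligned to ``ref_pos``, or None."""
        return self._ref_to_query.get(ref_pos)


def align_to_reference(
    query_protein: str,
    reference: str = BOVINE_RHODOPSIN,
    min_score: float = 0.0,
) -> SiteMap:
    """Globally align a query opsin to the numbering reference.

    Affine-gap global alignment under BLOSUM62 (open -11, extend -1);
    of co-optimal alignments the enumeration-first one is taken, which
    is deterministic for fixed inputs.  A score below ``min_score``
    signals a sequence too diverged to number reliably.
    """
    if not query_protein or not reference:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(reference.upper(), query_protein.upper())[0]
    if aln.score < min_score:
        raise ValueError(
            f"alignment score {aln.score} below sanity floor {min_score}; "
            "query does not look like an opsin"
        )
    pairs = []
    for (r0, r1), (q0, q1) in zip(*aln.aligned):
        for k in range(r1 - r0):
            pairs.append((r0 + k + 1, q0 + k + 1))
    return SiteMap(pairs=pairs, score=float(aln.score))


@dataclass
class TuningSiteProfile:
    """Residue sets observed at the canonical tuning sites.

    ``residues[site]`` is a frozenset of amino acids (size > 1 encodes
    heterozygosity or ambiguity) or None when the site falls in an
    unaligned/deleted region.
    """

    opsin_class: str
    residues: dict

    def known_sites(self):
        return [s for s, r in self.residues.items() if r]


def extract_profile(query_protein, site_map: SiteMap, opsin_class: str) -> TuningSiteProfile:
    """Pull the canonical-site residues for ``opsin_class`` out of a query.

    ``query_protein`` is an amino-acid string or a per-position list of
    amino-acid sets (the latter propagates codon ambiguity).
    """
    if opsin_class not in OPSIN_CLASSES:
        raise ValueError(f"opsin_class must be one of {OPSIN_CLASSES}")
    if isinstance(query_protein, str):
        cells = [frozenset(a) for a in query_protein.upper()]
    else:
        cells = [frozenset(a) for a in query_protein]
    residues = {}
    for site in CANONICAL_SITES[opsin_class]:
        q = site_map.query_position(site)
        if q is None or q > len(cells):
            residues[site] = None
        else:
            aa = cells[q - 1]
            residues[site] = None if aa >= frozenset("ACDEFGHIKLMNPQRSTVWY") else aa
    if not any(residues.values()):
        raise ValueError("no canonical tuning site could be read; profile unusable")
    return TuningSiteProfile(opsin_class=opsin_class, residues=residues)


@dataclass
class SpectralRuleSet:
    """Literature tuning rules for one opsin class.

    ``base_profile`` lists the residues of the reference long-wavelength
    pigment at the scored sites and ``base_lambda`` its lambda_max (nm).
    ``combination_entries`` map a frozenset of (site, residue)
    substitutions away from base to a measured lambda_max and take
    precedence over the additive sum of ``substitution_shifts`` (signed
    nm per single substitution), because measured combinations deviate
    from strict additivity by ~1 nm in several cases.
    ``qualitative_rules`` map a substitution to a direction-of-shift
    label with no numeric claim (e.g. the UV->violet shift of SWS1).
    """

    opsin_class: str
    base_profile: dict  # site -> residue
    base_lambda: float
    combination_entries: dict = field(default_factory=dict)
    substitution_shifts: dict = field(default_factory=dict)  # (site, residue) -> delta nm
    qualitative_rules: dict = field(default_factory=dict)  # (site, residue) -> label
    base_label: str | None = None
    qualitative_labels: dict = field(default_factory=dict)  # (site, residue) -> class label


def default_rules(opsin_class: str) -> SpectralRuleSet:
    """The package's built-in rule tables (vertebrate literature values)."""
    if opsin_class == "LWS":
        return SpectralRuleSet(
            opsin_class="LWS",
            base_profile={164: "S", 181: "H", 261: "Y", 269: "T", 292: "A"},
            base_lambda=560.0,
            combination_entries={
                frozenset(): 560.0,
                frozenset({(164, "A")}): 553.0,
                frozenset({(164, "A"), (261, "F")}): 545.0,
                frozenset({(164, "A"), (269, "A")}): 537.0,
            },
            substitution_shifts={
                (164, "A"): -7.0,
                (181, "Y"): -28.0,
                (261, "F"): -8.0,
                (269, "A"): -15.0,
                (292, "S"): -27.0,
            },
        )
    if opsin_class == "RH1":
        return SpectralRuleSet(
            opsin_class="RH1",
            base_profile={83: "D", 292: "A", 299: "S"},
            base_lambda=500.0,
            combination_entries={
                frozenset(): 500.0,
                frozenset({(83, "N"), (299, "A")}): 493.0,
                frozenset({(83, "N"), (292, "S"), (299, "A")}): 483.0,
            },
            substitution_shifts={
                (83, "N"): -6.0,
                (292, "S"): -10.0,
                (299, "A"): -2.0,
            },
        )
    if opsin_class == "SWS1":
        return SpectralRuleSet(
            opsin_class="SWS1",
            base_profile={86: "F"},
            base_lambda=360.0,
            base_label="UVS",
            combination_entries={frozenset(): 360.0},
            qualitative_rules={(86, "V"): "violet-shifted"},
            qualitative_labels={(86, "V"): "VS"},
        )
    raise ValueError(f"no default rules for opsin class {opsin_class!r}")


def _parse_sub(token: str):
    # "164A" -> (164, "A")
    i = 0
    while i < len(token) and token[i].isdigit():
        i += 1
    return int(token[:i]), token[i:]


def rules_from_text(text: str) -> SpectralRuleSet:
    """Parse a rule table from the documented key=value format.

    Lines (``#`` comments allowed)::

        class=LWS
        base_lambda=560
        base=164:S,181:H,261:Y,269:T,292:A
        combo=164A:553            # empty left side = base combination
        combo=164A+261F:545
        shift=164A:-7
        qualitative=86V:violet-shifted:VS
    """
    cls = None
    base_lambda = None
    base = {}
    combos, shifts, quals, qlabels = {}, {}, {}, {}
    base_label = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "class":
            cls = val
        elif key == "base_lambda":
            base_lambda = float(val)
        elif key == "base_label":
            base_label = val
        elif key == "base":
            for item in val.split(","):
                site, _, aa = item.partition(":")
                base[int(site)] = aa.strip()
        elif key == "combo":
            subs, _, lam = val.rpartition(":")
            key_set = frozenset(_parse_sub(t) for t in subs.split("+") if t)
            combos[key_set] = float(lam)
        elif key == "shift":
            sub, _, delta = val.partition(":")
            shifts[_parse_sub(sub)] = float(delta)
        elif key == "qualitative":
            parts = val.split(":")
            sub = _parse_sub(parts[0])
            quals[sub] = parts[1]
            if len(parts) > 2:
                qlabels[sub] = parts[2]
        else:
            raise ValueError(f"unknown rule key {key!r}")
    if cls is None or base_lambda is None:
        raise ValueError("rule table must declare class= and base_lambda=")
    combos.setdefault(frozenset(), base_lambda)
    return SpectralRuleSet(
        opsin_class=cls,
        base_profile=base,
        base_lambda=base_lambda,
        combination_entries=combos,
        substitution_shifts=shifts,
        qualitative_rules=quals,
        base_label=base_label,
        qualitative_labels=qlabels,
    )


@dataclass
class PredictionEntry:
    lambda_nm: float | None
    provenance: str  # "combination" | "additive" | "qualitative"
    label: str | None  # e.g. UVS / VS / violet-shifted
    residues: dict  # site -> residue for this resolved haplotype
    flags: tuple = ()


@dataclass
class SpectralPrediction:
    opsin_class: str
    entries: list  # of PredictionEntry


def predict_lambda_max(
    profile: TuningSiteProfile,
    rules: SpectralRuleSet | None = None,
    max_combinations: int = 16,
) -> SpectralPrediction:
    """Predict lambda_max for every resolved residue combination.

    Heterozygous/ambiguous sites are resolved by Cartesian product
    (capped at ``max_combinations``).  Unknown sites assume the base
    residue and are flagged.  A matching combination entry wins over
    the additive sum; substitutions with neither a combination nor a
    shift entry contribute 0 nm and are flagged ``unscored``.
    """
    if rules is None:
        rules = default_rules(profile.opsin_class)
    if rules.opsin_class != profile.opsin_class:
        raise ValueError(
            f"profile class {profile.opsin_class} does not match rules class {rules.opsin_class}"
        )
    scored_sites = sorted(rules.base_profile)
    site_options = []
    base_flags = []
    for site in scored_sites:
        obs = profile.residues.get(site)
        if not obs:
            site_options.append([rules.base_profile[site]])
            base_flags.append(f"assumed_base:{site}")
        else:
            site_options.append(sorted(obs))
    n_combo = 1
    for opts in site_options:
        n_combo *= len(opts)
    if n_combo > max_combinations:
        raise ValueError(
            f"{n_combo} residue combinations exceed cap {max_combinations}"
        )

    entries = []
    for combo in product(*site_options):
        residues = dict(zip(scored_sites, combo))
        subs = frozenset(
            (site, aa) for site, aa in residues.items() if aa != rules.base_profile[site]
        )
        flags = list(base_flags)
        qual = [s for s in subs if s in rules.qualitative_rules]
        if qual and subs <= set(rules.qualitative_rules):
            # purely qualitative substitutions: no numeric claim
            (sub,) = qual[:1]
            entries.append(
                PredictionEntry(
                    lambda_nm=None,
                    provenance="qualitative",
                    label=rules.qualitative_labels.get(sub, rules.qualitative_rules[sub]),
                    residues=residues,
                    flags=tuple(flags + [f"qualitative:{rules.qualitative_rules[sub]}"]),
                )
            )
            continue
        if subs in rules.combination_entries:
            entries.append(
                PredictionEntry(
                    lambda_nm=rules.combination_entries[subs],
                    provenance="combination",
                    label=rules.base_label,
                    residues=residues,
                    flags=tuple(flags),
                )
            )
            continue
        lam = rules.base_lambda
        for sub in sorted(subs):
            if sub in rules.substitution_shifts:
                lam += rules.substitution_shifts[sub]
            else:
                flags.append(f"unscored:{sub[0]}{sub[1]}")
        entries.append(
            PredictionEntry(
                lambda_nm=lam,
                provenance="additive",
                label=rules.base_label,
                residues=residues,
                flags=tuple(flags),
            )
        )
    return SpectralPrediction(opsin_class=profile.opsin_class, entries=entries)
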