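"""Reference numbering, tuning-site extraction and lambda-max rules."""

import pytest

import opsinevol as ov
from opsinevol.tuning import BOVINE_RHODOPSIN, default_rules


def _profile(cls, residues=None):
    rules = default_rules(cls)
    full = {s: frozenset(rules.base_profile[s]) for s in rules.base_profile}
    for s, aa in (residues or {}).items():
        full[int(s)] = frozenset(aa) if not isinstance(aa, frozenset) else aa
    return ov.TuningSiteProfile(cls, full)


class TestSiteMap:
    def test_identity(self):
        sm = ov.align_to_reference(BOVINE_RHODOPSIN)
        assert sm.pairs == [(i, i) for i in range(1, len(BOVINE_RHODOPSIN) + 1)]

    def test_internal_deletion_offsets(self):
        query = BOVINE_RHODOPSIN[:9] + BOVINE_RHODOPSIN[12:]
        sm = ov.align_to_reference(query)
        assert sm.query_position(5) == 5
        assert sm.query_position(20) == 17
        assert all(sm.query_position(p) is None for p in (10, 11, 12))

    def test_n_terminal_extension(self):
        sm = ov.align_to_reference("GPGRA" + BOVINE_RHODOPSIN)
        assert sm.query_position(1) == 6

    def test_coordinates_strictly_increasing(self):
        sm = ov.align_to_reference("MA" + BOVINE_RHODOPSIN[40:300])
        refs = [r for r, _ in sm.pairs]
        qrys = [q for _, q in sm.pairs]
        assert refs == sorted(refs) and qrys == sorted(qrys)

    def test_sanity_floor(self):
        with pytest.raises(ValueError, match="sanity floor"):
            ov.align_to_reference("KKKK", min_score=100.0)
        with pytest.raises(ValueError, match="empty"):
            ov.align_to_reference("")


class TestExtractProfile:
    def test_substituted_site(self):
        dna, _ = ov.make_opsin_fixture(ov.FixtureSpec(opsin_class="SWS1", residues={86: "V"}))
        prot = ov.translate_fixture(dna)
        sm = ov.align_to_reference("".join(sorted(a)[0] for a in prot))
        prof = ov.extract_profile(prot, sm, "SWS1")
        assert prof.residues[86] == frozenset("V")

    def test_heterozygous_site(self):
        dna, _ = ov.make_opsin_fixture(
            ov.FixtureSpec(opsin_class="SWS1", residues={86: {"F", "V"}})
        )
        prot = ov.translate_fixture(dna)
        sm = ov.align_to_reference("".join(sorted(a)[0] if len(a) == 1 else "X" for a in prot))
        prof = ov.extract_profile(prot, sm, "SWS1")
        assert prof.residues[86] == frozenset({"F", "V"})

    def test_deleted_site_unknown(self):
        dna, _ = ov.make_opsin_fixture(ov.FixtureSpec(opsin_class="LWS", deletions=(292,)))
        prot = ov.translate_fixture(dna)
        sm = ov.align_to_reference("".join(sorted(a)[0] for a in prot))
        prof = ov.extract_profile(prot, sm, "LWS")
        assert prof.residues[292] is None
        assert prof.residues[164] == frozenset("S")

    def test_all_unknown_is_error(self):
        sm = ov.SiteMap(pairs=[(1, 1)], score=0.0)
        with pytest.raises(ValueError, match="unusable"):
            ov.extract_profile("M", sm, "LWS")


class TestPredictLambdaMax:
    @pytest.mark.parametrize(
        "cls,residues,expected",
        [
            ("LWS", {}, 560.0),
            ("LWS", {164: "A"}, 553.0),
            ("LWS", {164: "A", 261: "F"}, 545.0),
            ("LWS", {164: "A", 269: "A"}, 537.0),
            ("RH1", {}, 500.0),
            ("RH1", {83: "N", 299: "A"}, 493.0),
            ("RH1", {83: "N", 292: "S", 299: "A"}, 483.0),
            ("SWS1", {}, 360.0),
        ],
    )
    def test_combination_table(self, cls, residues, expected):
        pred = ov.predict_lambda_max(_profile(cls, residues))
        assert [e.lambda_nm for e in pred.entries] == [expected]
        assert pred.entries[0].provenance == "combination"

    def test_additive_full_shift(self):
        prof = _profile("LWS", {164: "A", 181: "Y", 261: "F", 269: "A", 292: "S"})
        pred = ov.predict_lambda_max(prof)
        assert pred.entries[0].lambda_nm == pytest.approx(560 - (7 + 28 + 8 + 15 + 27))
        assert pred.entries[0].provenance == "additive"

    def test_additive_order_independence(self):
        # additive total must not depend on substitution enumeration order
        import itertools

        subs = {164: "A", 269: "A", 292: "S"}
        vals = set()
        for perm in itertools.permutations(subs.items()):
            prof = _profile("LWS", dict(perm))
            # avoid the combination entry by including 292S
            vals.add(ov.predict_lambda_max(prof).entries[0].lambda_nm)
        assert vals == {560 - 7 - 15 - 27}

    def test_base_profile_exact(self):
        for cls in ("LWS", "RH1", "SWS1"):
            pred = ov.predict_lambda_max(_profile(cls))
            assert pred.entries[0].lambda_nm == default_rules(cls).base_lambda

    def test_sws1_heterozygote_two_pigments(self):
        pred = ov.predict_lambda_max(_profile("SWS1", {86: frozenset("FV")}))
        got = {(e.lambda_nm, e.provenance, e.label) for e in pred.entries}
        assert got == {(360.0, "combination", "UVS"), (None, "qualitative", "VS")}

    def test_unknown_site_assumes_base_and_flags(self):
        prof = ov.TuningSiteProfile(
            "RH1", {83: frozenset("N"), 292: None, 299: frozenset("S")}
        )
        pred = ov.predict_lambda_max(prof)
        e = pred.entries[0]
        assert e.lambda_nm == pytest.approx(494.0)
        assert "assumed_base:292" in e.flags

    def test_unscored_substitution_contributes_zero(self):
        pred = ov.predict_lambda_max(_profile("LWS", {181: "G", 164: "A"}))
        e = pred.entries[0]
        assert e.lambda_nm == pytest.approx(553.0)  # only 164A scored
        assert any(f.startswith("unscored:181") for f in e.flags)

    def test_class_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            ov.predict_lambda_max(_profile("LWS"), rules=default_rules("RH1"))

    def test_combination_cap(self):
        prof = _profile("LWS", {s: frozenset("AS") for s in (164, 181, 261, 269, 292)})
        with pytest.raises(ValueError, match="cap"):
            ov.predict_lambda_max(prof, max_combinations=8)


class TestRuleConfig:
    def test_roundtrip_through_text(self):
        text = """
        # LWS rules
        class=LWS
        base_lambda=560
        base=164:S,181:H,261:Y,269:T,292:A
        combo=164A:553
        combo=164A+261F:545
        shift=164A:-7
        shift=292S:-27
        qualitative=86V:violet-shifted:VS
        """
        rules = ov.rules_from_text(text)
        assert rules.base_profile[181] == "H"
        assert rules.combination_entries[frozenset({(164, "A"), (261, "F")})] == 545.0
        assert rules.substitution_shifts[(292, "S")] == -27.0
        assert rules.qualitative_rules[(86, "V")] == "violet-shifted"
        pred = ov.predict_lambda_max(_profile("LWS", {164: "A"}), rules)
        assert pred.entries[0].lambda_nm == 553.0


def test_fixture_truth_consistency():
    """predict(extract(fixture)) reproduces the fixture's declared truth."""
    cases = [
        ("LWS", {164: "A", 269: "A"}),
        ("RH1", {83: "N", 292: "S", 299: "A"}),
        ("SWS1", {86: {"F", "V"}}),
    ]
    for cls, residues in cases:
        dna, truth = ov.make_opsin_fixture(ov.FixtureSpec(opsin_class=cls, residues=residues))
        prot = ov.translate_fixture(dna)
        sm = ov.align_to_reference("".join(sorted(a)[0] if len(a) == 1 else "X" for a in prot))
        prof = ov.extract_profile(prot, sm, cls)
        pred = ov.predict_lambda_max(prof)
        assert [e.lambda_nm for e in pred.entries] == truth["lambda_max"]
        assert [e.label for e in pred.entries] == truth["labels"]
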