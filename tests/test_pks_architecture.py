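"""Module grammar, DH triad, KR fingerprints, functionality, β-states."""

import numpy as np
import pytest

from lactamine.architectures import (
    domain_sequence,
    module_spec,
    modules_from_specs,
    template_modules,
)
from lactamine.pks_architecture import (
    DomainAnnotation,
    PKSModule,
    assess_functionality,
    beta_state,
    check_dh_triad,
    classify_kr,
    classify_at_substrate,
    parse_modules,
    read_domain_table,
    scan_domains,
    write_domain_table,
)
from lactamine.synthetic_data import render_protein


class TestParseModules:
    def test_mte_layout_gives_ten_extension_modules(self):
        mods = template_modules("mte")
        extensions = [m for m in mods if not m.is_loading]
        assert len(extensions) == 10
        assert [m.index for m in extensions] == list(range(1, 11))
        assert sum(m.is_loading for m in mods) == 1

    def test_eleven_extension_modules(self):
        mods = template_modules("bom")
        assert len([m for m in mods if not m.is_loading]) == 11

    def test_single_ks_at_acp_gene_one_module_not_loading(self):
        mods = modules_from_specs([module_spec(kr=None)])
        assert len(mods) == 1
        assert not mods[0].is_loading
        assert mods[0].domain_kinds == ["KS", "AT", "ACP"]

    def test_acp_count_equals_module_count(self):
        for name in ("mte", "pac", "bom"):
            mods = template_modules(name)
            n_acp = sum(m.domain_kinds.count("ACP") for m in mods)
            assert n_acp == len(mods)

    def test_invariant_to_coordinate_offsets(self):
        specs = [module_spec(kr="B", dh="active"), module_spec(kr=None)]
        a = modules_from_specs(specs)

        def shifted(offset):
            mods = modules_from_specs(specs)
            for m in mods:
                for d in m.domains:
                    d.aa_start += offset
                    d.aa_end += offset
            return mods

        b = shifted(1_000)
        assert [m.domain_kinds for m in a] == [m.domain_kinds for m in b]
        assert [m.functional for m in a] == [m.functional for m in b]


class TestDHTriad:
    def test_complete_triad(self):
        assert check_dh_triad("XXHABLGALRFPXXXXDLLAQXX")

    def test_his_substitution_breaks_triad(self):
        assert not check_dh_triad("XXAABLGALRFPXXXXDLLAQXX")

    def test_missing_downstream_asp(self):
        assert not check_dh_triad("XXHABLGALRFPXXXXELLAQXX")

    def test_empty_or_short(self):
        assert not check_dh_triad("")
        assert not check_dh_triad("HAB")


class TestClassifyKR:
    def test_fixture_fingerprints(self):
        assert classify_kr(domain_sequence("KR", {"class": "B"})) == "B"
        assert classify_kr(domain_sequence("KR", {"class": "A"})) == "A"
        assert classify_kr(domain_sequence("KR", {"class": "u"})) == "unassigned"

    def test_both_motifs_is_conflict(self):
        seq = "AMKVALVTGGTGGLG" + "AELDDAAWAA"
        with pytest.warns(UserWarning):
            assert classify_kr(seq) == "unassigned"

    def test_no_rossmann_motif_unassigned(self):
        assert classify_kr("LDDWWLDD") == "unassigned"
        assert classify_kr("") == "unassigned"

    def test_never_assigns_without_fingerprint(self):
        """Property: sequences lacking both fingerprints stay unassigned."""
        rng = np.random.default_rng(0)
        alphabet = list("AEFIKLMNQRTVY")  # no W, cannot spell LDD
        for _ in range(50):
            seq = "GAGAAG" + "".join(rng.choice(alphabet, size=60))
            assert classify_kr(seq) == "unassigned"

    def test_at_substrate_motifs(self):
        assert classify_at_substrate(domain_sequence("AT", {"substrate": "methylmalonyl"})) == "methylmalonyl"
        assert classify_at_substrate(domain_sequence("AT", {"substrate": "malonyl"})) == "malonyl"
        assert classify_at_substrate("AAAA") == "unknown"


def _module_with(kinds, dh_active=True, kr_class="B"):
    domains = []
    pos = 0
    for k in kinds:
        props = {}
        if k == "DH":
            props = {"active": dh_active}
        elif k == "KR":
            props = {"class": kr_class}
        seq = domain_sequence(k, props)
        d = DomainAnnotation(kind=k, aa_start=pos, aa_end=pos + len(seq), sequence=seq)
        if k == "DH":
            d.motif_flags["DH_triad_complete"] = dh_active
        if k == "KR":
            d.motif_flags["KR_fingerprint"] = {"A": "W_present", "B": "LDD_present"}.get(kr_class, "none")
        domains.append(d)
        pos += len(seq) + 10
    mod = PKSModule(index=1, gene_locus="t", domains=domains)
    mod.kr_class = kr_class if "KR" in kinds else "absent"
    mod.functional = assess_functionality(mod)
    return mod


class TestFunctionality:
    @pytest.mark.parametrize(
        "kinds, dh_active, expected",
        [
            (["AT", "DH", "KR", "ACP"], True, False),       # KS missing
            (["KS", "AT", "DH", "ACP"], False, False),      # no KR + dead DH
            (["KS", "AT", "DH", "KR", "ACP"], True, True),  # full
            (["KS", "AT", "ACP"], True, True),              # minimal
            (["KS", "AT", "DH", "ACP"], True, True),        # no KR, live DH
        ],
    )
    def test_functionality_rules(self, kinds, dh_active, expected):
        assert _module_with(kinds, dh_active).functional is expected

    def test_loading_module_exempt(self):
        mod = PKSModule(index=0, gene_locus="t", domains=[], is_loading=True)
        assert assess_functionality(mod)

    def test_pure_function_of_domain_multiset(self):
        """Functionality depends only on domains + flags, not on order/coords."""
        rng = np.random.default_rng(1)
        pool = ["KS", "AT", "DH", "ER", "KR", "ACP"]
        for _ in range(30):
            kinds = [k for k in pool if rng.random() < 0.7]
            dh_active = bool(rng.random() < 0.5)
            a = _module_with(kinds, dh_active)
            shuffled = list(kinds)
            rng.shuffle(shuffled)
            b = _module_with(shuffled, dh_active)
            assert a.functional == b.functional


class TestBetaState:
    @pytest.mark.parametrize(
        "kinds, kr_class, expected",
        [
            (["KS", "AT", "ACP"], None, "ketone"),
            (["KS", "AT", "KR", "ACP"], "A", "hydroxyl_S"),
            (["KS", "AT", "KR", "ACP"], "B", "hydroxyl_R"),
            (["KS", "AT", "KR", "ACP"], "u", "hydroxyl"),
            (["KS", "AT", "DH", "KR", "ACP"], "B", "enoyl"),
            (["KS", "AT", "DH", "ER", "KR", "ACP"], "B", "methylene"),
        ],
    )
    def test_reductive_loop_states(self, kinds, kr_class, expected):
        mod = _module_with(kinds, True, kr_class or "u")
        assert beta_state(mod) == expected

    def test_error_on_nonfunctional(self):
        mod = _module_with(["AT", "ACP"])
        with pytest.raises(ValueError):
            beta_state(mod)


class TestScanner:
    def test_scanner_recovers_template_domain_order(self):
        rng = np.random.default_rng(9)
        specs = [
            [("KS", {}), ("AT", {"substrate": "methylmalonyl"}),
             ("DH", {"active": True}), ("KR", {"class": "B"}), ("ACP", {})],
            [("KS", {}), ("AT", {"substrate": "malonyl"}), ("KR", {"class": "A"}), ("ACP", {})],
        ]
        protein = render_protein(specs, rng)
        domains = scan_domains(protein)
        assert [d.kind for d in domains] == ["KS", "AT", "DH", "KR", "ACP", "KS", "AT", "KR", "ACP"]
        kr_b, kr_a = [d for d in domains if d.kind == "KR"]
        assert kr_b.motif_flags["KR_fingerprint"] == "LDD_present"
        assert kr_a.motif_flags["KR_fingerprint"] == "W_present"
        at1, at2 = [d for d in domains if d.kind == "AT"]
        assert at1.at_substrate == "methylmalonyl"
        assert at2.at_substrate == "malonyl"
        dh = next(d for d in domains if d.kind == "DH")
        assert dh.motif_flags["DH_triad_complete"]

    def test_dead_dh_found_but_degenerate(self):
        rng = np.random.default_rng(10)
        protein = render_protein([[("KS", {}), ("AT", {}), ("DH", {"active": False}), ("ACP", {})]], rng)
        domains = scan_domains(protein)
        dh = next(d for d in domains if d.kind == "DH")
        assert dh.motif_flags["DH_triad_complete"] is False

    def test_domain_table_round_trip(self, tmp_path):
        mods = template_modules("pac")
        annotated = [("pacP1", [d for m in mods[:3] for d in m.domains])]
        p = tmp_path / "domains.tsv"
        write_domain_table(annotated, p)
        back = read_domain_table(p)
        assert len(back) == 1
        locus, domains = back[0]
        assert locus == "pacP1"
        assert [d.kind for d in domains] == [d.kind for d in annotated[0][1]]
        assert [d.motif_flags for d in domains] == [d.motif_flags for d in annotated[0][1]]
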