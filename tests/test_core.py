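"""Registry, pedigree, and genotype-summary behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glshet.panels import class_proportions, genotype_means, total_gsl
from glshet.pedigree import Genotype, Pedigree, Role
from glshet.registry import (
    CompoundDef,
    GSLClass,
    analytes,
    build_registry,
    registry_from_frame,
    registry_frame,
    validate_registry,
)

ABBRS = [c.abbreviation for c in analytes()]


class TestRegistry:
    def test_composition_of_registry(self):
        reg = build_registry()
        assert len(analytes(reg)) == 13
        counts = {cls: sum(1 for c in analytes(reg) if c.gsl_class is cls) for cls in GSLClass}
        assert counts == {
            GSLClass.ALIPHATIC_3C: 3,
            GSLClass.ALIPHATIC_4C: 5,
            GSLClass.INDOLYL: 4,
            GSLClass.AROMATIC: 1,
        }

    def test_sinigrin_and_gns_classes(self):
        reg = {c.abbreviation: c for c in build_registry()}
        assert reg["SIN"].gsl_class is GSLClass.ALIPHATIC_3C
        aromatic_analytes = [c for c in analytes() if c.gsl_class is GSLClass.AROMATIC]
        assert [c.abbreviation for c in aromatic_analytes] == ["GNS"]

    def test_internal_standard_is_gtp_aromatic(self):
        (is_,) = [c for c in build_registry() if c.is_internal_standard]
        assert is_.abbreviation == "GTP"
        assert is_.gsl_class is GSLClass.AROMATIC

    def test_duplicate_abbreviation_rejected(self):
        reg = build_registry() + [CompoundDef("SIN", "dup", "dup", GSLClass.INDOLYL)]
        with pytest.raises(ValueError, match="duplicate"):
            validate_registry(reg)

    def test_two_internal_standards_rejected(self):
        reg = build_registry() + [
            CompoundDef("XX", "x", "x", GSLClass.AROMATIC, is_internal_standard=True)
        ]
        with pytest.raises(ValueError, match="internal standard"):
            validate_registry(reg)

    def test_frame_round_trip(self):
        assert registry_from_frame(registry_frame()) == build_registry()


class TestPedigree:
    def test_hybrid_parent_must_be_line(self):
        with pytest.raises(ValueError, match="expected LINE"):
            Pedigree(
                [
                    Genotype("L1", Role.LINE),
                    Genotype("L2", Role.LINE),
                    Genotype("H1", Role.HYBRID, "L1", "L2"),
                    Genotype("H2", Role.HYBRID, "H1", "L2"),  # hybrid parent
                ]
            )

    def test_line_with_parents_rejected(self):
        with pytest.raises(ValueError, match="must not carry parent"):
            Pedigree([Genotype("L1", Role.LINE), Genotype("L2", Role.LINE, "L1", None)])

    def test_missing_parent_rejected(self):
        with pytest.raises(ValueError, match="unknown parent"):
            Pedigree([Genotype("L1", Role.LINE), Genotype("H1", Role.HYBRID, "L1", "L9")])

    def test_frame_round_trip(self, pedigree):
        again = Pedigree.from_frame(pedigree.to_frame())
        assert set(again.genotypes) == set(pedigree.genotypes)
        assert {g.genotype_id for g in again.hybrids} == {g.genotype_id for g in pedigree.hybrids}


class TestGenotypeMeans:
    def _panel(self, values, gid="g", compound="SIN"):
        return pd.DataFrame(
            {
                "genotype_id": gid,
                "replicate": range(1, len(values) + 1),
                "compound": compound,
                "umol_per_g_dw": values,
            }
        )

    def test_arithmetic_mean(self):
        gm = genotype_means(self._panel([2.0, 4.0]))
        assert gm.mean.loc["g", "SIN"] == 3.0

    def test_single_replicate_se_undefined(self):
        gm = genotype_means(self._panel([5.0]))
        assert gm.mean.loc["g", "SIN"] == 5.0
        assert np.isnan(gm.se.loc["g", "SIN"])

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            genotype_means(pd.DataFrame(columns=["genotype_id", "replicate", "compound", "umol_per_g_dw"]))

    def test_recovers_simulated_means(self, rng):
        # 4·σ/√n recovery band around known genotype means
        sigma, n = 0.5, 200
        true = {"A": 10.0, "B": 3.0}
        rows = []
        for gid, mu in true.items():
            for r, v in enumerate(rng.normal(mu, sigma, size=n)):
                rows.append({"genotype_id": gid, "replicate": r, "compound": "SIN", "umol_per_g_dw": v})
        gm = genotype_means(pd.DataFrame(rows))
        for gid, mu in true.items():
            assert abs(gm.mean.loc[gid, "SIN"] - mu) < 4 * sigma / np.sqrt(n)


class TestTotalAndProportions:
    def test_total_trivials(self):
        zeros = pd.Series(0.0, index=ABBRS)
        assert total_gsl(zeros) == 0.0
        assert total_gsl(pd.Series(1.0, index=ABBRS)) == 13.0

    def test_total_excludes_internal_standard(self):
        row = pd.Series(1.0, index=ABBRS + ["GTP"])
        assert total_gsl(row) == 13.0

    def test_total_missing_compound_errors(self):
        with pytest.raises(ValueError, match="missing"):
            total_gsl(pd.Series(1.0, index=ABBRS[:-1]))

    @given(scale=st.floats(min_value=0.01, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_total_is_linear(self, scale):
        row = pd.Series(np.linspace(0.1, 5.0, 13), index=ABBRS)
        assert total_gsl(row * scale) == pytest.approx(scale * total_gsl(row))

    def test_single_compound_proportion(self):
        m = pd.DataFrame(0.0, index=["g"], columns=ABBRS)
        m.loc["g", "SIN"] = 2.5
        props = class_proportions(m)
        assert props.loc["g", "ALIPHATIC_3C"] == 1.0
        assert props.loc["g"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_one_compound_per_class_equal_mass(self):
        m = pd.DataFrame(0.0, index=["g"], columns=ABBRS)
        for comp in ("SIN", "GNP", "GBS", "GNS"):  # one per class
            m.loc["g", comp] = 1.0
        props = class_proportions(m)
        assert np.allclose(props.loc["g"], 0.25)

    def test_rows_sum_to_one(self, means):
        props = class_proportions(means)
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_genotype_errors(self):
        m = pd.DataFrame(0.0, index=["g"], columns=ABBRS)
        with pytest.raises(ValueError, match="all-zero"):
            class_proportions(m)

    def test_planted_class_split_recovered(self):
        # forward-simulated panel targeting a 73/26.9/0.1 aliphatic/indolyl/aromatic split
        from glshet.registry import class_of

        target = {"ALIPHATIC": 0.730, "INDOLYL": 0.269, "AROMATIC": 0.001}
        rng = np.random.default_rng(11)
        rows = []
        n_ali = sum(1 for a in ABBRS if class_of(a).value.startswith("ALIPHATIC"))
        n_ind = sum(1 for a in ABBRS if class_of(a) is GSLClass.INDOLYL)
        for g in range(6):
            for a in ABBRS:
                cls = class_of(a)
                share = (
                    target["ALIPHATIC"] / n_ali
                    if cls.value.startswith("ALIPHATIC")
                    else target["INDOLYL"] / n_ind
                    if cls is GSLClass.INDOLYL
                    else target["AROMATIC"]
                )
                for r in range(3):
                    rows.append(
                        {
                            "genotype_id": f"g{g}",
                            "replicate": r,
                            "compound": a,
                            "umol_per_g_dw": 42.0 * share * rng.lognormal(0, 0.05),
                        }
                    )
        props = class_proportions(genotype_means(pd.DataFrame(rows)).mean)
        aliphatic = props["ALIPHATIC_3C"] + props["ALIPHATIC_4C"]
        assert aliphatic.mean() == pytest.approx(0.730, abs=0.02)
        assert props["INDOLYL"].mean() == pytest.approx(0.269, abs=0.02)
        assert props["AROMATIC"].mean() == pytest.approx(0.001, abs=0.005)
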