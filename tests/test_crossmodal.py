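"""Cross-modal universe construction and the temporal concordance profile."""

import numpy as np
import pandas as pd
import pytest

from concord.correlation import spearman_rho_p
from concord.crossmodal import (
    GENE_THRESHOLDS,
    PROTEIN_THRESHOLDS,
    CrossModalMap,
    PKCurve,
    build_universe,
    project_protein_table,
    temporal_concordance,
)
from concord.overlap import overlap_counts, permutation_overlap_p
from concord.signatures import SignatureThresholds, call_signature
from concord.simulate import SyntheticSpec, gen_crossmodal_pair
from conftest import make_table


def cmap_of(pairs, policy="best_p"):
    return CrossModalMap(pd.DataFrame(pairs, columns=["gene_id", "protein_id"]), policy)


class TestBuildUniverse:
    def test_direct_intersection(self):
        u = build_universe({"g1", "g2", "g3"}, {"p1", "p2"}, cmap_of([("g1", "p1"), ("g2", "p2")]))
        assert u.analyte_ids == {"g1", "g2"}
        assert u.provenance == "cross-modal"
        assert u.source_sizes == (3, 2)

    def test_many_to_many_collapses_to_one_entry(self):
        u = build_universe({"g1"}, {"p1", "p2"}, cmap_of([("g1", "p1"), ("g1", "p2")]))
        assert len(u) == 1

    def test_untested_gene_excluded(self):
        u = build_universe({"g2"}, {"p1", "p2"}, cmap_of([("g1", "p1"), ("g2", "p2")]))
        assert u.analyte_ids == {"g2"}

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_universe({"g1"}, {"p9"}, cmap_of([("g1", "p1")]))

    def test_order_independent_and_idempotent(self):
        pairs = [("g1", "p1"), ("g2", "p2"), ("g3", "p3")]
        u1 = build_universe(["g1", "g2", "g3"], ["p1", "p2"], cmap_of(pairs))
        u2 = build_universe(["g3", "g2", "g1"], ["p2", "p1"], cmap_of(pairs[::-1]))
        assert u1.analyte_ids == u2.analyte_ids
        u3 = build_universe(u1.analyte_ids, ["p1", "p2"], cmap_of(pairs))
        assert u3.analyte_ids == u1.analyte_ids

    def test_generator_controlled_sizes(self):
        sim = gen_crossmodal_pair(SyntheticSpec(n_genes=2000, seed=5))
        prot_ids = set()
        for _, t in sim.csf_series:
            prot_ids |= set(t.analyte_ids)
        u = build_universe(sim.neuronal.analyte_ids, prot_ids, sim.cmap)
        assert len(u) == 1235


class TestProjection:
    def test_best_p_collapse(self):
        prot = make_table(["p1", "p2"], [1.0, -2.0], [0.5, 0.001], modality="protein")
        proj = project_protein_table(prot, cmap_of([("g1", "p1"), ("g1", "p2")]))
        assert list(proj.analyte_ids) == ["g1"]
        assert proj.data.loc[0, "log2fc"] == -2.0

    def test_mean_lfc_collapse(self):
        prot = make_table(["p1", "p2"], [1.0, -2.0], [0.5, 0.001], modality="protein")
        proj = project_protein_table(prot, cmap_of([("g1", "p1"), ("g1", "p2")], "mean_lfc"))
        assert proj.data.loc[0, "log2fc"] == pytest.approx(-0.5)
        assert proj.data.loc[0, "p_value"] == pytest.approx(0.001)


class TestTemporalConcordance:
    def test_identity_map_identical_tables_rho_one(self):
        ids = [f"g{i}" for i in range(60)]
        rng = np.random.default_rng(0)
        lfc = rng.normal(0, 2, 60)
        p = np.clip(np.abs(rng.normal(0, 0.02, 60)) + 1e-6, None, 1.0)
        gene = make_table(ids, lfc, p)
        prot = make_table(ids, lfc, p, modality="protein", agent="ketamine")
        cmap = cmap_of([(g, g) for g in ids])
        prof = temporal_concordance(
            gene, [(24.0, prot)], cmap,
            protein_thresholds=SignatureThresholds(0.05, 0.0, use_adjusted=False),
            n_perm=200, seed=1,
        )
        assert prof.table.loc[0, "rho"] == pytest.approx(1.0)
        assert prof.table.loc[0, "overlap_count"] == prof.table.loc[0, "n_gene_sig"]

    def test_single_timepoint_matches_standalone_ops(self):
        """The profile row reproduces overlap_stats + correlation run by hand."""
        sim = gen_crossmodal_pair(SyntheticSpec(n_genes=2000, seed=11))
        h, prot_tab = sim.csf_series[3]
        prof = temporal_concordance(sim.neuronal, [(h, prot_tab)], sim.cmap, n_perm=501, seed=9)
        prot_ids = set(prot_tab.analyte_ids)
        uni = build_universe(sim.neuronal.analyte_ids, prot_ids, sim.cmap)
        neuro = sim.neuronal.restrict(uni)
        proj = project_protein_table(prot_tab, sim.cmap, uni)
        gsig = call_signature(neuro, GENE_THRESHOLDS)
        psig = call_signature(proj, PROTEIN_THRESHOLDS)
        t = overlap_counts(gsig, psig, uni)
        assert prof.table.loc[0, "overlap_count"] == t.a
        assert prof.table.loc[0, "n_gene_sig"] == len(gsig)
        assert prof.table.loc[0, "n_protein_sig"] == len(psig)
        shared = sorted(gsig.members & psig.members)
        res = spearman_rho_p(
            neuro.indexed().loc[shared, "log2fc"], proj.indexed().loc[shared, "log2fc"], method="t"
        )
        assert prof.table.loc[0, "rho"] == pytest.approx(res.rho)

    def test_planted_peak_recovered(self):
        sim = gen_crossmodal_pair(SyntheticSpec(n_genes=2000, seed=21))
        prof = temporal_concordance(sim.neuronal, sim.csf_series, sim.cmap, n_perm=299, seed=2)
        peak = sim.truth["peak_index"]
        assert prof.argmax_rho() == peak
        # enrichment ramps: overlap at the peak clearly exceeds the first draw
        assert prof.table.loc[peak, "overlap_count"] > prof.table.loc[0, "overlap_count"]

    def test_null_series_flat_profile(self):
        sim = gen_crossmodal_pair(SyntheticSpec(n_genes=2000, crossmodal_enrichment=1.0, seed=31))
        prof = temporal_concordance(sim.neuronal, sim.csf_series, sim.cmap, n_perm=299, seed=4)
        assert (prof.table["overlap_p_perm"] > 0.001).all()
        # null overlap ~ 21, so |rho| should stay within ~3 null SDs (1/sqrt(n-3))
        assert prof.table["rho"].abs().max() < 0.7
        assert prof.table["rho"].abs().median() < 0.35

    def test_small_overlap_flagged_but_continues(self):
        ids = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(3)
        gene = make_table(ids, rng.normal(0, 2, 40), [0.5] * 39 + [0.001])
        prot = make_table(ids, rng.normal(0, 2, 40), [0.001] + [0.5] * 39, modality="protein")
        cmap = cmap_of([(g, g) for g in ids])
        prof = temporal_concordance(
            gene, [(6.0, prot)], cmap,
            protein_thresholds=SignatureThresholds(0.05, 0.0, use_adjusted=False),
            n_perm=99, seed=0,
        )
        assert np.isnan(prof.table.loc[0, "rho"])
        assert prof.table.loc[0, "overlap_count"] == 0

    def test_nonincreasing_hours_rejected(self):
        sim = gen_crossmodal_pair(SyntheticSpec(n_genes=2000, seed=1))
        series = [sim.csf_series[1], sim.csf_series[0]]
        with pytest.raises(ValueError, match="increasing"):
            temporal_concordance(sim.neuronal, series, sim.cmap, n_perm=9, seed=0)

    def test_q_is_bh_of_p(self):
        from concord.correlation import bh_fdr

        sim = gen_crossmodal_pair(SyntheticSpec(n_genes=2000, seed=13))
        prof = temporal_concordance(sim.neuronal, sim.csf_series, sim.cmap, n_perm=99, seed=0)
        ok = prof.table["p"].notna()
        np.testing.assert_allclose(
            prof.table.loc[ok, "q"], bh_fdr(prof.table.loc[ok, "p"].to_numpy())
        )


class TestProfilePlot:
    def test_plot_with_pk_overlay_writes_file(self, tmp_path):
        from concord.crossmodal import plot_profile

        sim = gen_crossmodal_pair(SyntheticSpec(n_genes=1500, seed=2))
        prof = temporal_concordance(sim.neuronal, sim.csf_series, sim.cmap, n_perm=49, seed=0)
        pk = PKCurve([1, 2, 4, 8, 12, 24], [1.0, 0.8, 0.5, 0.3, 0.2, 0.1], "ketamine")
        out = tmp_path / "profile.png"
        plot_profile(prof, [pk], out)
        assert out.stat().st_size > 0


class TestPKCurve:
    def test_validation(self):
        with pytest.raises(ValueError):
            PKCurve([1, 1, 2], [0.1, 0.2, 0.3], "ketamine")
        with pytest.raises(ValueError):
            PKCurve([1, 2], [0.1, -0.2], "HNK")
        PKCurve([1, 2, 4], [0.1, 0.9, 0.3], "HNK")
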