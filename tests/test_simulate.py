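"""Synthetic-data generator: distributions, noise models, determinism."""

import hashlib
import json

import dendropy
import numpy as np
import pandas as pd
import pytest

from mutdfe import SimConfig, write_dataset
from mutdfe.config import AssayConfig, DFEMixture, ExpressionConfig, TreeConfig
from mutdfe.dfe import fit_gpd
from mutdfe.fitness import replicate_fitness, CompetitionReplicate
from mutdfe.phylo import is_bifurcating
from mutdfe.simulate import (MARKER_CONTROL_ID, simulate_competitions,
                             simulate_expression, simulate_gene,
                             simulate_mutation_set, simulate_tree_and_states,
                             simulate_true_dfe, simulate_trna_table)


def _cfg(**kw) -> SimConfig:
    base = dict(seed=3, n_syn=12, n_nonsyn=20, n_nonsense=3,
                gene_length_codons=120,
                assay=AssayConfig(n_replicates=3, colonies_sampled=200),
                tree=TreeConfig(n_tips=10))
    base.update(kw)
    return SimConfig(**base)


class TestTrueDFE:
    def test_table_shape_and_classes(self):
        df = simulate_true_dfe(_cfg())
        assert len(df) == 35
        assert (df["class"].value_counts()["synonymous"] == 12)

    def test_no_beneficial_when_p_zero(self):
        cfg = _cfg(dfe_mixture=DFEMixture(p_beneficial=0.0))
        df = simulate_true_dfe(cfg)
        sense = df[df["class"] != "nonsense"]
        assert (sense["true_w"] <= 1.0).all()

    def test_kappa_minus_one_bounded_by_tau(self):
        cfg = _cfg(n_syn=5000, n_nonsyn=0, n_nonsense=0,
                   dfe_mixture=DFEMixture(p_beneficial=1.0, tail_kappa=-1.0,
                                          tail_tau=0.1))
        s = simulate_true_dfe(cfg)["true_w"] - 1
        assert s.max() <= 0.1 + 1e-12
        assert s.min() >= 0

    def test_gpd_mean_oracle(self):
        """Mean of beneficial s matches tau/(1-kappa) within 3 SE."""
        tau, kappa, n = 0.05, -0.35, 10_000
        cfg = _cfg(n_syn=n, n_nonsyn=0, n_nonsense=0,
                   dfe_mixture=DFEMixture(p_beneficial=1.0, tail_tau=tau,
                                          tail_kappa=kappa))
        s = (simulate_true_dfe(cfg)["true_w"] - 1).to_numpy()
        mean_expected = tau / (1 - kappa)           # ~0.037
        sd = tau / ((1 - kappa) * np.sqrt(1 - 2 * kappa))
        assert abs(s.mean() - mean_expected) < 3 * sd / np.sqrt(n)

    def test_gpd_tail_recovery(self):
        """A GPD fit to 10,000 simulated beneficial draws recovers kappa
        within 0.1 and tau within 15%."""
        cfg = _cfg(n_syn=10_000, n_nonsyn=0, n_nonsense=0,
                   dfe_mixture=DFEMixture(p_beneficial=1.0))
        s = (simulate_true_dfe(cfg)["true_w"] - 1).to_numpy()
        fit = fit_gpd(s)
        assert abs(fit.kappa - (-0.35)) < 0.1
        assert abs(fit.tau - 0.05) / 0.05 < 0.15

    def test_nonsense_strongly_deleterious(self):
        df = simulate_true_dfe(_cfg(n_nonsense=200))
        nonsense = df[df["class"] == "nonsense"]["true_w"]
        sense = df[df["class"] != "nonsense"]["true_w"]
        assert nonsense.max() < 1.0
        assert nonsense.mean() < sense.mean()

    def test_invalid_gpd_rejected(self):
        cfg = _cfg(dfe_mixture=DFEMixture(tail_kappa=-2.0))
        with pytest.raises(ValueError):
            simulate_true_dfe(cfg)


class TestCompetitions:
    def test_counts_sum_to_plate_size(self):
        cfg = _cfg()
        comp = simulate_competitions(simulate_true_dfe(cfg), cfg)
        N = cfg.assay.colonies_sampled
        assert ((comp.mutant_initial + comp.ref_initial) == N).all()
        assert ((comp.mutant_final + comp.ref_final) == N).all()

    def test_neutral_expected_frequency(self):
        cfg = _cfg(n_syn=200, n_nonsyn=0, n_nonsense=0,
                   dfe_mixture=DFEMixture(p_beneficial=0, neutral_sd=0,
                                          p_deleterious=0),
                   assay=AssayConfig(n_replicates=1, colonies_sampled=2000))
        comp = simulate_competitions(simulate_true_dfe(cfg), cfg)
        f1 = comp.mutant_final / 2000
        assert abs(f1.mean() - 0.5) < 0.01

    def test_deterministic_growth_formula(self):
        # w=1.1, d=6.7, f0=0.5 -> final mutant frequency 1.1^6.7/(1.1^6.7+1)
        expected = 1.1 ** 6.7 / (1.1 ** 6.7 + 1)
        assert expected == pytest.approx(0.655, abs=1e-3)
        cfg = _cfg(assay=AssayConfig(n_replicates=200, colonies_sampled=10_000,
                                     doublings=6.7))
        truth = pd.DataFrame({"mutation_id": ["m1"], "class": ["synonymous"],
                              "true_w": [1.1]})
        comp = simulate_competitions(truth, cfg, include_marker_control=False)
        assert np.isclose((comp.mutant_final / 10_000).mean(), expected,
                          atol=0.005)

    def test_large_plate_inversion(self):
        """colonies -> 1e6: the recomputed w matches true w to 3 decimals."""
        cfg = _cfg(assay=AssayConfig(n_replicates=1, colonies_sampled=10 ** 6))
        truth = pd.DataFrame({"mutation_id": ["m1"], "class": ["synonymous"],
                              "true_w": [1.07]})
        comp = simulate_competitions(truth, cfg, include_marker_control=False)
        r = comp.iloc[0]
        w_hat = replicate_fitness(CompetitionReplicate(
            "m1", int(r.mutant_initial), int(r.ref_initial),
            int(r.mutant_final), int(r.ref_final), float(r.doublings)))
        assert w_hat == pytest.approx(1.07, abs=5e-4)

    def test_marker_control_rows(self):
        cfg = _cfg()
        comp = simulate_competitions(simulate_true_dfe(cfg), cfg)
        assert (comp.mutation_id == MARKER_CONTROL_ID).sum() == cfg.assay.n_replicates

    def test_nonpositive_w_rejected(self):
        cfg = _cfg()
        bad = pd.DataFrame({"mutation_id": ["m1"], "class": ["x"], "true_w": [0.0]})
        with pytest.raises(ValueError):
            simulate_competitions(bad, cfg)


class TestExpression:
    def test_noiseless_identity(self):
        cfg = _cfg(expression=ExpressionConfig(slope=1.0, intercept=0.0,
                                               noise_sd=0.0))
        truth = simulate_true_dfe(cfg)
        expr = simulate_expression(truth, cfg)
        assert np.allclose(expr["relative_expression"], truth["true_w"])

    def test_noiseless_regression_r2_one(self):
        from mutdfe.permreg import PermutationOLS
        cfg = _cfg(expression=ExpressionConfig(noise_sd=0.0))
        truth = simulate_true_dfe(cfg)
        expr = simulate_expression(truth, cfg)
        res = PermutationOLS(truth["true_w"],
                             expr[["relative_expression"]]).fit(B=20, seed=0)
        assert res.adj_r_squared == pytest.approx(1.0)

    def test_slope_recovery_within_3se(self):
        import statsmodels.api as sm
        cfg = _cfg(n_syn=27, n_nonsyn=0, n_nonsense=0)
        truth = simulate_true_dfe(cfg)
        expr = simulate_expression(truth, cfg)
        fit = sm.OLS(expr["relative_expression"],
                     sm.add_constant(truth["true_w"])).fit()
        assert abs(fit.params.iloc[1] - cfg.expression.slope) < 3 * fit.bse.iloc[1]


class TestTreeAndStates:
    def test_no_polytomies_when_fraction_zero(self):
        cfg = _cfg(tree=TreeConfig(n_tips=20, polytomy_fraction=0.0))
        nwk, _ = simulate_tree_and_states(cfg, simulate_true_dfe(cfg))
        t = dendropy.Tree.get(data=nwk, schema="newick", rooting="force-rooted")
        assert is_bifurcating(t)

    def test_polytomies_created(self):
        cfg = _cfg(tree=TreeConfig(n_tips=30, polytomy_fraction=0.4))
        nwk, _ = simulate_tree_and_states(cfg, simulate_true_dfe(cfg))
        t = dendropy.Tree.get(data=nwk, schema="newick", rooting="force-rooted")
        polys = sum(1 for nd in t.preorder_internal_node_iter()
                    if len(nd.child_nodes()) > 2)
        assert polys > 0

    def test_states_binary_and_complete(self):
        cfg = _cfg()
        truth = simulate_true_dfe(cfg)
        _, states = simulate_tree_and_states(cfg, truth)
        assert set(states["state"]) <= {0, 1}
        assert len(states) == cfg.tree.n_tips * len(truth)

    def test_zero_slope_presence_independent(self):
        cfg = _cfg(n_syn=400, n_nonsyn=0, n_nonsense=0,
                   tree=TreeConfig(n_tips=8, presence_logit_slope=0.0,
                                   presence_logit_intercept=0.0))
        truth = simulate_true_dfe(cfg)
        _, states = simulate_tree_and_states(cfg, truth)
        present = states.groupby("site")["state"].max()
        # intercept 0 -> presence probability exactly 0.5 regardless of w
        assert abs(present.mean() - 0.5) < 0.08

    def test_positive_slope_recovered_downstream(self):
        from mutdfe.phylo import PresenceFitnessModel
        cfg = _cfg(n_syn=100, n_nonsyn=100, n_nonsense=0,
                   tree=TreeConfig(n_tips=8, presence_logit_slope=25.0,
                                   presence_logit_intercept=-0.5))
        truth = simulate_true_dfe(cfg)
        _, states = simulate_tree_and_states(cfg, truth)
        present = states.groupby("site")["state"].max()
        df = truth.set_index("mutation_id").join(present.rename("y"))
        res = PresenceFitnessModel(df["y"].to_numpy(),
                                   df["true_w"].to_numpy()).fit(B=None)
        assert res.slope > 0
        assert res.p_lrt < 0.05


class TestGeneAndDataset:
    def test_gene_valid_and_mutations_classified(self):
        cfg = _cfg()
        cds = simulate_gene(cfg)
        assert cds.n_codons == cfg.gene_length_codons + 1   # + stop
        muts = simulate_mutation_set(cds, cfg)
        assert muts["class"].value_counts().to_dict() == {
            "nonsynonymous": 20, "synonymous": 12, "nonsense": 3}

    def test_trna_table_decodes_everything(self):
        from mutdfe.mutations import TRNACopyTable
        df = simulate_trna_table(_cfg())
        table = TRNACopyTable(dict(zip(df["anticodon"], df["copies"])))
        W = table.absolute_adaptiveness()
        assert all(w > 0 for w in W.values())

    def test_byte_identical_outputs_under_same_config(self, tmp_path):
        cfg = _cfg()
        p1 = write_dataset(cfg, tmp_path / "a")
        p2 = write_dataset(cfg, tmp_path / "b")
        for name in p1:
            h1 = hashlib.sha256(p1[name].read_bytes()).hexdigest()
            h2 = hashlib.sha256(p2[name].read_bytes()).hexdigest()
            assert h1 == h2, name

    def test_different_seed_changes_outputs(self, tmp_path):
        paths1 = write_dataset(_cfg(seed=3), tmp_path / "a")
        paths2 = write_dataset(_cfg(seed=4), tmp_path / "b")
        assert (paths1["competitions.csv"].read_bytes()
                != paths2["competitions.csv"].read_bytes())

    def test_truth_json_roundtrip(self, small_dataset, small_config):
        truth = json.loads(small_dataset["truth.json"].read_text())
        assert truth["config"]["seed"] == small_config.seed
        assert len(truth["true_w"]) == (small_config.n_syn +
                                        small_config.n_nonsyn +
                                        small_config.n_nonsense)
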