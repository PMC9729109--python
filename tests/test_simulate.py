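"""The synthetic-data generator must match its own statistical model."""

import numpy as np
import pandas as pd
import pytest

from sedadna.damage import MismatchMatrix
from sedadna.geochron import BurialConfig
from sedadna.lca import decode_mismatches
from sedadna.simulate import (
    DamageParams,
    SimulationConfig,
    make_taxonomy_and_refs,
    make_temperature_history,
    simulate_geochron_inputs,
    simulate_hit_table,
    simulate_reads,
)


def tally_truth(reads: dict, truth: pd.DataFrame, k_positions: int = 15):
    """Positional substitution frequencies straight from the truth table."""
    m = MismatchMatrix(k_positions)
    for rec in truth.itertuples(index=False):
        m.add_read(1, reads[rec.read_id], decode_mismatches(rec.injected))
    return m.counts[1]


class TestTaxonomyAndRefs:
    def test_minimal_call_gives_single_lineage(self):
        tax, refs = make_taxonomy_and_refs(1, 1, 1000, seed=7)
        assert len(tax) == 4
        (sp,) = refs
        assert tax.lineage(sp) == [1, 10, 100, sp]
        assert len(refs[sp]) == 1000

    def test_sibling_identity_matches_configured_divergence(self):
        div = 0.03
        tax, refs = make_taxonomy_and_refs(3, 2, 5000, seed=1, sibling_divergence=div)
        assert len(refs) == 6
        by_genus = {}
        for sp in refs:
            by_genus.setdefault(tax.parent[sp], []).append(sp)
        for genus, (a, b) in by_genus.items():
            sa = np.frombuffer(refs[a].encode(), dtype=np.uint8)
            sb = np.frombuffer(refs[b].encode(), dtype=np.uint8)
            observed = (sa != sb).mean()
            assert observed == pytest.approx(div, abs=0.01)

    def test_seed_reproducibility(self):
        _, refs_a = make_taxonomy_and_refs(3, 2, 5000, seed=1)
        _, refs_b = make_taxonomy_and_refs(3, 2, 5000, seed=1)
        assert refs_a == refs_b

    @pytest.mark.parametrize("bad", [(0, 1, 1000), (1, 0, 1000), (1, 1, 50)])
    def test_invalid_sizes_rejected(self, bad):
        with pytest.raises(ValueError):
            make_taxonomy_and_refs(*bad, seed=0)


class TestReads:
    def test_terminal_damage_frequency_matches_model(self, sim_bundle):
        """Empirical C->T at positions 1..15 fits A(1-q)^(x-1)+c within
        3 binomial standard errors at 20k reads."""
        dmg = sim_bundle["config"].damage
        counts = tally_truth(sim_bundle["reads"], sim_bundle["truth"])
        x = np.arange(1, 16)
        expected = dmg.rate(x)
        for k, n in ((counts.k5, counts.n5), (counts.k3, counts.n3)):
            freq = k / n
            se = np.sqrt(expected * (1 - expected) / n)
            assert np.all(np.abs(freq - expected) <= 3 * se)

    def test_full_contamination_means_background_only(self):
        tax, refs = make_taxonomy_and_refs(2, 1, 4000, seed=3)
        config = SimulationConfig(
            taxon_abundances={sp: 1.0 for sp in refs},
            contamination_fraction=1.0,
            n_reads=20_000,
            seed=4,
        )
        reads, truth, _ = simulate_reads(refs, config)
        assert not truth["damaged"].any()
        counts = tally_truth(reads, truth)
        f1 = counts.k5[0] / counts.n5[0]
        se = np.sqrt(0.01 * 0.99 / counts.n5[0])
        assert abs(f1 - config.damage.c) <= 3 * se

    def test_fragment_mean_is_respected(self, sim_bundle):
        realized = sim_bundle["truth"]["length"].mean()
        assert realized == pytest.approx(50.0, rel=0.05)
        assert sim_bundle["truth"]["length"].min() >= 30

    def test_seed_determinism_and_truth_bijection(self, sim_bundle):
        reads2, truth2, _ = simulate_reads(sim_bundle["refs"], sim_bundle["config"])
        assert reads2 == sim_bundle["reads"]
        pd.testing.assert_frame_equal(truth2, sim_bundle["truth"])
        # bijection: every emitted read appears exactly once in the truth table
        assert sorted(truth2["read_id"]) == sorted(reads2)
        assert truth2["read_id"].is_unique

    def test_empty_refs_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads({}, SimulationConfig(n_reads=10))

    def test_invalid_damage_params_rejected(self):
        with pytest.raises(ValueError):
            DamageParams(a=0.9, q=0.3, c=0.2)  # a + c > 1
        with pytest.raises(ValueError):
            DamageParams(a=0.1, q=1.5, c=0.01)


class TestHitTable:
    def test_lone_undamaged_species_hits_at_full_identity(self):
        tax, refs = make_taxonomy_and_refs(1, 1, 2000, seed=5)
        config = SimulationConfig(
            taxon_abundances={sp: 1.0 for sp in refs},
            damage=DamageParams(a=0.2, q=0.3, c=1e-9),
            contamination_fraction=1.0,  # undamaged reads, background ~ 0
            n_reads=50,
            seed=5,
        )
        reads, truth, _ = simulate_reads(refs, config)
        hits = simulate_hit_table(reads, truth, refs, tax, seed=5)
        assert (hits.groupby("read_id").size() == 1).all()
        assert (hits["identity"] == 1.0).all()
        assert (hits["mismatches"] == ".").all()

    def test_sibling_identity_gap_matches_divergence(self, sim_bundle):
        hits = sim_bundle["hits"]
        truth = sim_bundle["truth"]
        src = dict(zip(truth["read_id"], truth["taxon"]))
        gaps = []
        for read_id, sub in hits.groupby("read_id"):
            if len(sub) == 2:
                own = sub[sub["node"] == src[read_id]]["identity"]
                other = sub[sub["node"] != src[read_id]]["identity"]
                if len(own) == 1 and len(other) == 1:
                    gaps.append(float(own.iloc[0]) - float(other.iloc[0]))
        # sibling divergence 3% -> mean identity gap close to 3 points
        assert np.mean(gaps) == pytest.approx(0.03, abs=0.005)

    def test_mismatch_lists_consistent_with_identity(self, sim_bundle):
        hits = sim_bundle["hits"].sample(n=300, random_state=0)
        for rec in hits.itertuples(index=False):
            mms = decode_mismatches(rec.mismatches)
            assert rec.identity == pytest.approx(1 - len(mms) / rec.length, abs=1e-9)
            assert all(1 <= p <= rec.length for p, _, _ in mms)

    def test_seed_gives_identical_tables(self, sim_bundle):
        again = simulate_hit_table(
            sim_bundle["reads"], sim_bundle["truth"], sim_bundle["refs"],
            sim_bundle["taxonomy"], seed=1,
        )
        pd.testing.assert_frame_equal(again, sim_bundle["hits"])

    def test_unknown_read_rejected(self, sim_bundle):
        bad_truth = sim_bundle["truth"].copy()
        bad_truth.loc[bad_truth.index[0], "read_id"] = "nonexistent"
        with pytest.raises(ValueError, match="nonexistent"):
            simulate_hit_table(
                sim_bundle["reads"], bad_truth.head(1), sim_bundle["refs"],
                sim_bundle["taxonomy"],
            )


class TestGeochronInputs:
    def test_zero_noise_zero_age_gives_exact_ratio(self):
        pairs, _ = simulate_geochron_inputs(0.0, r0=6.75, noise_cv=0.0, seed=0)
        assert np.allclose(pairs["n26"] / pairs["n10"], 6.75)

    def test_one_differential_half_life_halves_the_ratio(self):
        config = BurialConfig(r0=6.75)
        t_half = np.log(2) / (config.lam26 - config.lam10)
        pairs, _ = simulate_geochron_inputs(t_half, r0=6.75, noise_cv=0.0, seed=0)
        assert np.allclose(pairs["n26"] / pairs["n10"], 6.75 / 2)

    def test_constant_history_reproduces_requested_mat(self):
        _, history = simulate_geochron_inputs(
            1.0, temperature_spec={"kind": "constant", "mat_c": -17.0}, seed=0
        )
        assert np.allclose(history.temperature([0.0, 1e5, 2e6]), 256.15)

    def test_glacial_cycles_alternate_between_levels(self):
        history = make_temperature_history(
            {
                "kind": "glacial_cycles",
                "present_mat_c": -17.0,
                "glacial_cooling_c": 10.0,
                "period_yr": 100_000.0,
                "glacial_fraction": 0.5,
                "duration_yr": 1.0e6,
            }
        )
        temps = history.temperature(np.array([10_000.0, 60_000.0]))
        assert temps[0] == pytest.approx(256.15)
        assert temps[1] == pytest.approx(246.15)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            simulate_geochron_inputs(-1.0)
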