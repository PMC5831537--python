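"""The synthetic benchmark generator: determinism, planted mechanisms,
taxonomy structure and abundance coupling."""

import filecmp

import numpy as np
import pytest

from phagehost.composition import canonical_kmer_profile, profile_distance
from phagehost.exact_match import build_seed_index, longest_exact_match
from phagehost.simulate import (
    MODES,
    FixtureConfig,
    build_benchmark,
    load_bundle,
    make_hosts,
    save_bundle,
)
from phagehost.taxonomy import RANKS, ranks_shared

SMALL = dict(n_hosts=6, host_len=6000, n_phages=10, phage_len=2500,
             shared_gene_len=600, n_samples=30)


class TestConfig:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            FixtureConfig(coupling=1.5)
        with pytest.raises(ValueError):
            FixtureConfig(prophage_fraction=-0.1)

    def test_positive_sizes_enforced(self):
        with pytest.raises(ValueError):
            FixtureConfig(n_hosts=0)


class TestDeterminism:
    def test_same_seed_byte_identical_bundle(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        save_bundle(build_benchmark(FixtureConfig(seed=5, **SMALL)), a)
        save_bundle(build_benchmark(FixtureConfig(seed=5, **SMALL)), b)
        names = [p.name for p in a.iterdir()]
        match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
        assert sorted(match) == sorted(names)
        assert not mismatch and not errors

    def test_different_seed_different_sequences_same_schema(self, tmp_path):
        b1 = build_benchmark(FixtureConfig(seed=1, **SMALL))
        b2 = build_benchmark(FixtureConfig(seed=2, **SMALL))
        assert b1.hosts[0].seq != b2.hosts[0].seq
        assert set(b1.manifest) == set(b2.manifest)
        assert [p["mode"] for p in b1.manifest["phages"]] == [
            p["mode"] for p in b2.manifest["phages"]
        ]

    def test_save_load_round_trip(self, tmp_path):
        bundle = build_benchmark(FixtureConfig(seed=3, **SMALL))
        save_bundle(bundle, tmp_path / "x")
        back = load_bundle(tmp_path / "x")
        assert [r.seq for r in back.hosts] == [r.seq for r in bundle.hosts]
        assert back.truth == bundle.truth
        assert back.modes == bundle.modes
        assert back.lineages == bundle.lineages
        assert np.allclose(back.phage_abundance.to_numpy(),
                           bundle.phage_abundance.to_numpy())


class TestHosts:
    def test_lineage_table_is_tree_consistent(self, default_bundle):
        lineages = default_bundle.lineages
        # same name at rank r implies same name at every higher rank
        for a in lineages.values():
            for b in lineages.values():
                shared = ranks_shared(a, b)
                for low, high in zip(RANKS[:-1], RANKS[1:]):
                    assert (low not in shared) or (high in shared)

    def test_bias_strength_separates_host_profiles(self):
        """At full bias, a genome half is far closer to its own other half
        than to other hosts (k=4); at zero bias the margin collapses."""
        def margins(bias, seed):
            rng = np.random.default_rng(seed)
            hosts, _ = make_hosts(FixtureConfig(host_bias=bias, n_hosts=8, host_len=20_000), rng)
            halves = [
                (canonical_kmer_profile(h.seq[:10_000], 4), canonical_kmer_profile(h.seq[10_000:], 4))
                for h in hosts
            ]
            own, cross = [], []
            for i, (a1, a2) in enumerate(halves):
                own.append(profile_distance(a1, a2))
                for j, (b1, _) in enumerate(halves):
                    if i != j:
                        cross.append(profile_distance(a1, b1))
            return np.array(own), np.array(cross)

        own1, cross1 = margins(1.0, 11)
        assert (own1[:, None] < cross1[None, :]).mean() >= 0.95
        own0, cross0 = margins(0.0, 11)
        # null case: self and cross distances overlap heavily
        assert (own0[:, None] < cross0[None, :]).mean() < 0.95


class TestPlantedMechanisms:
    def test_mode_rotation_covers_all_mechanisms(self, default_bundle):
        counts = {m: 0 for m in MODES}
        for m in default_bundle.modes.values():
            counts[m] += 1
        assert all(v == len(default_bundle.modes) / len(MODES) for v in counts.values())

    def test_unknown_mode_rejected(self):
        from phagehost.simulate import make_phage
        from phagehost.sequence import SequenceRecord

        rng = np.random.default_rng(0)
        host = SequenceRecord("h", "ACGT" * 1000)
        with pytest.raises(ValueError):
            make_phage(host, FixtureConfig(), "mystery", rng, "p")

    def test_prophage_segment_recovered_exactly(self):
        config = FixtureConfig(seed=7, **SMALL)
        bundle = build_benchmark(config)
        hosts_by_id = {h.id: h for h in bundle.hosts}
        index = build_seed_index(list(hosts_by_id.values()))
        seg_len = round(config.prophage_fraction * config.phage_len)
        for pid, mode in bundle.modes.items():
            if mode != "prophage":
                continue
            phage = next(p for p in bundle.phages if p.id == pid)
            m = longest_exact_match(phage, bundle.truth[pid], index)
            assert m is not None and m.length >= seg_len

    def test_spacer_donor_mismatch_budgets(self, default_bundle):
        """Planted spacers carry 0/1/2 substitutions: they qualify at
        max_mismatch=2 but not all at 0."""
        from phagehost.crispr import crispr_spacer_count_scores

        donors = [p for p, m in default_bundle.modes.items() if m == "spacer_donor"][:2]
        phages = [p for p in default_bundle.phages if p.id in donors]
        hosts = [h for h in default_bundle.hosts
                 if h.id in {default_bundle.truth[p] for p in donors}]
        strict = crispr_spacer_count_scores(phages, hosts, max_mismatch=0)
        loose = crispr_spacer_count_scores(phages, hosts, max_mismatch=2)
        for pid in donors:
            hid = default_bundle.truth[pid]
            assert loose.scores.loc[pid, hid] == 3
            strict_count = strict.scores.loc[pid, hid]
            assert np.isnan(strict_count) or strict_count < 3

    def test_composition_only_phages_carry_no_exact_match_beyond_chance(
        self, default_bundle, default_report
    ):
        """Cross-talk control: amelioration must not plant verbatim
        sequence, so exact-match lengths stay at chance level."""
        table = default_report.tables["exact_match"]
        comp_rows = [p for p, m in default_bundle.modes.items() if m == "composition_only"]
        # biased backgrounds legitimately stretch chance matches into the
        # tens of bases; anything near the planted scales (600/12000 bp)
        # would mean amelioration leaked verbatim sequence
        assert table.scores.loc[comp_rows].to_numpy().max() < 150

    def test_abundance_only_sequences_unrelated(self, default_bundle, default_report):
        table = default_report.tables["exact_match"]
        ab_rows = [p for p, m in default_bundle.modes.items() if m == "abundance_only"]
        assert table.scores.loc[ab_rows].to_numpy().max() < 150


class TestAbundanceCoupling:
    def test_perfect_coupling_gives_unit_correlation(self):
        from phagehost.abundance import pair_correlation
        from phagehost.simulate import simulate_abundance

        config = FixtureConfig(coupling=1.0, phage_dropout=0.0, n_samples=30)
        rng = np.random.default_rng(0)
        truth = {"p": "h"}
        pmat, hmat = simulate_abundance(truth, {"p": "abundance_only"}, ["h"], config, rng)
        r = pair_correlation(pmat.loc["p"].to_numpy(), hmat.loc["h"].to_numpy())
        assert r == pytest.approx(1.0)

    def test_sparse_overlap_triggers_no_evidence(self):
        """With only 6 mutually non-zero samples the pair is excluded."""
        from phagehost.abundance import pair_correlation

        rng = np.random.default_rng(1)
        x = np.zeros(30)
        y = np.zeros(30)
        keep = rng.choice(30, size=6, replace=False)
        x[keep] = rng.random(6) + 0.5
        y[keep] = x[keep] * 2
        y[(keep[0] + 1) % 30] = 1.0  # host present elsewhere too
        assert pair_correlation(x, y) is None
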