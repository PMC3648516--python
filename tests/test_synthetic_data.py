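import numpy as np
import pytest

from tagdge.synthetic_data import (
    SyntheticConfig,
    gene_of_transcript,
    make_annotation_map,
    make_truth,
    simulate_qpcr_panel,
    simulate_study,
    simulate_tag_libraries,
    simulate_transcriptomes,
    transcript_id,
    write_study,
)
from tagdge.tag_reference import build_tag_index, iter_tags


def tag_sets(transcriptomes, species):
    out = {}
    for sp in species:
        tags = set()
        for _, seq in transcriptomes[sp]:
            tags |= {t for _, t in iter_tags(seq)}
        out[sp] = tags
    return out


class TestSimulateTranscriptomes:
    def test_zero_divergence_identical_tag_sets(self):
        cfg = SyntheticConfig(n_genes=60, divergence=0.0, seed=5)
        tx, orthology = simulate_transcriptomes(cfg)
        sets = tag_sets(tx, cfg.species)
        assert sets["MED"] == sets["MEAM1"] == sets["AsiaII3"]
        assert len(orthology) == 60

    def test_same_seed_identical_output(self):
        cfg = SyntheticConfig(n_genes=40, seed=9)
        a, _ = simulate_transcriptomes(cfg)
        b, _ = simulate_transcriptomes(cfg)
        assert a == b

    def test_every_transcript_taggable(self):
        cfg = SyntheticConfig(n_genes=80, divergence=0.2, seed=3)
        tx, _ = simulate_transcriptomes(cfg)
        for sp in cfg.species:
            for tid, seq in tx[sp]:
                assert any(True for _ in iter_tags(seq)), tid

    def test_common_tag_survival_matches_per_window_oracle(self):
        """Fraction of genes keeping a three-species shared tag ~ per-site survival."""
        cfg = SyntheticConfig(n_genes=800, divergence=0.05, seed=17)
        tx, orthology = simulate_transcriptomes(cfg)
        seq_of = {
            sp: {gene_of_transcript(t): s for t, s in tx[sp]} for sp in cfg.species
        }
        rate = cfg.divergence / 2  # per-species per-site substitution rate
        survive_window = (1 - rate) ** (3 * 21)  # 21 sites intact in 3 species
        expected = 0.0
        observed = 0
        for gid in orthology:
            shared = None
            n_sites = None
            for sp in cfg.species:
                tags = {t for _, t in iter_tags(seq_of[sp][gid])}
                shared = tags if shared is None else shared & tags
            # oracle expectation from the MED copy's site count
            k = sum(1 for _ in iter_tags(seq_of["MED"][gid]))
            expected += 1 - (1 - survive_window) ** k
            if shared:
                observed += 1
        # binomial-scale tolerance around the analytic expectation
        sigma = np.sqrt(expected * (1 - expected / len(orthology)))
        assert abs(observed - expected) < 5 * max(sigma, 5.0)

    def test_orthology_map_structure(self):
        cfg = SyntheticConfig(n_genes=10, seed=1)
        _, orthology = simulate_transcriptomes(cfg)
        for gid, per_species in orthology.items():
            assert set(per_species) == set(cfg.species)
            for sp, tid in per_species.items():
                assert tid == transcript_id(gid, sp)
                assert gene_of_transcript(tid) == gid


class TestTruth:
    def test_tpm_sums_to_a_million(self):
        truth = make_truth(SyntheticConfig(n_genes=500, seed=2))
        for sp in truth.species:
            assert truth.tpm[sp].sum() == pytest.approx(1e6)

    def test_planted_effect_bookkeeping(self):
        cfg = SyntheticConfig(n_genes=400, de_fraction=0.2, effect_log2=2.0, seed=4)
        truth = make_truth(cfg)
        n_de = sum(
            int(np.any([truth.multiplier_log2[s][i] != 0 for s in cfg.species]))
            for i in range(cfg.n_genes)
        )
        assert n_de == round(0.2 * 400)
        for a, b in cfg.comparisons:
            planted = truth.planted_log2(a, b)
            assert set(np.unique(np.abs(planted[planted != 0]))) <= {2.0, 4.0}

    def test_no_effects_when_fraction_zero(self):
        truth = make_truth(SyntheticConfig(n_genes=100, de_fraction=0.0, seed=2))
        for a, b in SyntheticConfig(n_genes=100).comparisons:
            assert not truth.is_de(a, b).any()


class TestSimulateTagLibraries:
    def test_counts_track_expression_without_noise(self):
        cfg = SyntheticConfig(
            n_genes=150,
            library_depth=400_000,
            divergence=0.0,
            de_fraction=0.0,
            singleton_noise_rate=0.0,
            seed=6,
        )
        study = simulate_study(cfg)
        index = build_tag_index(study.transcriptomes["MED"], "MED")
        lib = study.libraries["MED"]
        assert lib.total == cfg.library_depth
        truth = study.truth
        idx = {g: i for i, g in enumerate(truth.gene_ids)}
        gene_counts = {}
        for tag, c in lib.counts.items():
            (tid,) = index.lookup(tag)
            gid = gene_of_transcript(tid)
            gene_counts[gid] = gene_counts.get(gid, 0) + c
        # multinomial moment check on well-expressed genes: |obs - exp| < 5 sd
        checked = 0
        for gid, obs in gene_counts.items():
            exp = truth.tpm["MED"][idx[gid]] / 1e6 * cfg.library_depth
            if exp > 200:
                assert abs(obs - exp) < 5 * np.sqrt(exp)
                checked += 1
        assert checked > 20

    def test_noise_mass_removed_by_cleaning(self):
        from tagdge.tag_library import clean_tags

        cfg = SyntheticConfig(
            n_genes=150, library_depth=300_000, singleton_noise_rate=0.1, seed=8
        )
        study = simulate_study(cfg)
        for sp in cfg.species:
            raw = study.libraries[sp]
            clean = clean_tags(raw)
            removed = (raw.total - clean.total) / raw.total
            # injected noise is exactly 10%; genuine singletons add a little
            assert 0.095 <= removed <= 0.13

    def test_planted_effect_recovered_in_counts(self):
        cfg = SyntheticConfig(
            n_genes=300,
            library_depth=1_000_000,
            divergence=0.0,
            de_fraction=0.1,
            effect_log2=2.0,
            singleton_noise_rate=0.0,
            seed=10,
        )
        study = simulate_study(cfg)
        truth = study.truth
        index = build_tag_index(study.transcriptomes["MED"], "MED")
        per_gene = {sp: {} for sp in ("MED", "MEAM1")}
        for sp in per_gene:
            for tag, c in study.libraries[sp].counts.items():
                hits = index.lookup(tag)
                if len(hits) == 1:
                    gid = gene_of_transcript(next(iter(hits)))
                    per_gene[sp][gid] = per_gene[sp].get(gid, 0) + c
        planted = truth.planted_log2("MED", "MEAM1")
        realized = truth.true_log2("MED", "MEAM1")  # includes renormalization
        checked = 0
        for i, gid in enumerate(truth.gene_ids):
            if planted[i] == 0:
                continue
            x = per_gene["MED"].get(gid, 0)
            y = per_gene["MEAM1"].get(gid, 0)
            if min(x, y) < 50:
                continue
            est = np.log2(x / y)
            # multinomial standard error of the log2 ratio estimator
            se = np.sqrt(1 / x + 1 / y) / np.log(2)
            assert abs(est - realized[i]) < max(0.3, 4 * se)
            checked += 1
        assert checked >= 5

    def test_determinism(self):
        cfg = SyntheticConfig(n_genes=50, library_depth=50_000, seed=12)
        a = simulate_study(cfg)
        b = simulate_study(cfg)
        for sp in cfg.species:
            assert a.libraries[sp].counts == b.libraries[sp].counts


class TestAnnotationAndQpcr:
    def test_annotation_sizes_and_planting(self, rng):
        genes = [f"g{i:05d}" for i in range(200)]
        ann = make_annotation_map(
            genes, rng, n_terms=30, planted={"PLANT": {"g00001", "g00002"}}
        )
        assert len(ann) == 31
        for t in ann.values():
            assert 2 <= len(t.genes) <= 80
            assert t.genes <= set(genes)
        assert ann["PLANT"].genes == {"g00001", "g00002"}

    def test_qpcr_panel_concordance_with_truth(self, rng):
        from tagdge.expression import direction_concordance, relative_expression_ddct

        cfg = SyntheticConfig(n_genes=300, de_fraction=0.2, seed=13)
        truth = make_truth(cfg)
        de_idx = np.where(truth.is_de("MED", "MEAM1"))[0][:10]
        panel = simulate_qpcr_panel(truth, ("MED", "MEAM1"), de_idx, rng)
        pairs = []
        for a, b in panel:
            qpcr_log2 = np.log2(relative_expression_ddct(a, b))
            i = truth.gene_ids.index(a.gene_id)
            pairs.append((truth.true_log2("MED", "MEAM1")[i], qpcr_log2))
        n_conc, n_tot = direction_concordance(pairs)
        assert n_tot == 10 and n_conc >= 9  # 4-fold effects dwarf CT noise


def test_write_study_emits_consumable_files(small_study, small_study_dir):
    d = small_study_dir
    cfg = small_study.config
    for sp in cfg.species:
        assert (d / f"{sp}.transcripts.fasta").exists()
        assert (d / f"{sp}.tags.tsv").exists()
    assert (d / "annotation.gmt.tsv").exists()
    assert (d / "truth.tsv").exists()
    # tag TSV reloads into the identical library
    from tagdge.tag_library import load_tag_counts

    lib = load_tag_counts(d / "MED.tags.tsv", "MED")
    assert lib.counts == small_study.libraries["MED"].counts


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(n_genes=0)
    with pytest.raises(ValueError):
        SyntheticConfig(divergence=0.5)
    with pytest.raises(ValueError):
        SyntheticConfig(de_fraction=1.5)
    with pytest.raises(ValueError):
        SyntheticConfig(gene_length=(10, 5))
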