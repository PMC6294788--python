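"""Synthetic cohort generator: determinism, dosage scaling, Mendelian truth."""

import numpy as np
import pandas as pd
import pytest

from dosecnv import SimConfig, read_cohort, simulate_cohort, write_cohort


def small_config(**overrides):
    params = dict(n_trios=2, n_duos=2, n_singletons=1, n_probes=400,
                  n_genes=60, seed=5)
    params.update(overrides)
    return SimConfig(**params)


# ---------------------------------------------------------------- config


def test_config_validation():
    with pytest.raises(ValueError, match="span"):
        SimConfig(n_probes=40, n_chromosomes=4, cnv_probe_span_range=(5, 20))
    with pytest.raises(ValueError, match="fraction"):
        SimConfig(de_novo_fraction=1.5)
    with pytest.raises(ValueError, match="copy"):
        SimConfig(copy_numbers=(2,))
    with pytest.raises(ValueError):
        SimConfig(cnv_probe_span_range=(0, 5))


def test_study_profile_matches_cohort_mix():
    cfg = SimConfig.study_profile(n_probes=4000)
    assert (cfg.n_trios, cfg.n_duos, cfg.n_singletons) == (98, 72, 20)
    assert cfg.n_samples == 98 * 3 + 72 * 2 + 20


# ---------------------------------------------------------------- determinism


def test_simulation_is_deterministic():
    a = simulate_cohort(small_config())
    b = simulate_cohort(small_config())
    pd.testing.assert_frame_equal(a.counts, b.counts)
    pd.testing.assert_frame_equal(a.expression, b.expression)
    pd.testing.assert_frame_equal(a.genotypes.table, b.genotypes.table)
    assert a.truth.planted_cnvs == b.truth.planted_cnvs
    # a different seed must change the depth matrix
    c = simulate_cohort(small_config(seed=6))
    assert not a.counts.equals(c.counts)


def test_written_cohorts_are_byte_identical(tmp_path):
    cohort = simulate_cohort(small_config())
    write_cohort(cohort, tmp_path / "a")
    write_cohort(cohort, tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


# ---------------------------------------------------------------- planting


def test_zero_rate_plants_nothing():
    cohort = simulate_cohort(small_config(cnv_rate_per_sample=0.0))
    assert cohort.truth.planted_cnvs == []
    assert cohort.genotypes.table.empty


def test_copy_over_two_scaling_of_depth():
    """Mean depth over CNV probes converges to copy/2 x baseline (3 SE)."""
    cfg = small_config(
        n_trios=0, n_duos=0, n_singletons=6, n_probes=800,
        cnv_probe_span_range=(50, 60), cnv_rate_per_sample=1.0,
        copy_numbers=(1,), batch_sd=0.0, depth_noise=0.0, seed=9,
    )
    cohort = simulate_cohort(cfg)
    assert cohort.truth.planted_cnvs, "expected planted events"
    col = {s: i for i, s in enumerate(cohort.samples)}
    for cnv in cohort.truth.planted_cnvs:
        probes = cohort.counts.to_numpy()[cnv.probe_lo: cnv.probe_hi + 1,
                                          col[cnv.sample]]
        expected = cfg.mean_depth * cnv.copy / 2
        se = np.sqrt(expected / len(probes))  # Poisson SE of the mean
        assert abs(probes.mean() - expected) < 3 * se


def test_zero_copy_deletion_has_no_reads():
    cfg = small_config(
        n_trios=0, n_duos=0, n_singletons=4, n_probes=800,
        cnv_probe_span_range=(50, 60), cnv_rate_per_sample=1.0,
        copy_numbers=(0,), seed=3,
    )
    cohort = simulate_cohort(cfg)
    col = {s: i for i, s in enumerate(cohort.samples)}
    for cnv in cohort.truth.planted_cnvs:
        probes = cohort.counts.to_numpy()[cnv.probe_lo: cnv.probe_hi + 1,
                                          col[cnv.sample]]
        assert probes.sum() == 0


def test_expression_scales_with_dosage_for_responders():
    cfg = small_config(
        n_trios=0, n_duos=0, n_singletons=6, n_probes=800, n_genes=100,
        cnv_probe_span_range=(50, 60), cnv_rate_per_sample=1.0,
        copy_numbers=(1,), responder_fraction=1.0, expr_cv=0.02, seed=13,
    )
    cohort = simulate_cohort(cfg)
    genes = cohort.gene_models
    found = 0
    for cnv in cohort.truth.planted_cnvs:
        hit = (genes["chrom"] == cnv.chrom) & (genes["start"] < cnv.end) & (
            genes["end"] > cnv.start)
        for gid in genes.loc[hit, "gene_id"]:
            row = cohort.expression.loc[gid]
            others = row.drop(cnv.sample).mean()
            assert row[cnv.sample] < 0.75 * others  # ~half expression
            found += 1
    assert found > 5


# ---------------------------------------------------------------- Mendelian truth


def test_truth_is_mendelian_consistent(default_cohort):
    cohort = default_cohort
    by_sample = {}
    for cnv in cohort.truth.planted_cnvs:
        by_sample.setdefault(cnv.sample, []).append(cnv)
    n_probes = len(cohort.probe_map)
    for cnv in cohort.truth.planted_cnvs:
        assert 0 <= cnv.probe_lo <= cnv.probe_hi < n_probes
        if cnv.origin in ("maternal", "paternal"):
            mother, father = cohort.pedigree.parents_of(cnv.sample)
            parent = mother if cnv.origin == "maternal" else father
            if parent is None:
                continue  # inherited from the ungenotyped duo parent
            carried = [
                p for p in by_sample.get(parent, [])
                if (p.chrom, p.start, p.end, p.copy) ==
                   (cnv.chrom, cnv.start, cnv.end, cnv.copy)
            ]
            assert len(carried) == 1
        elif cnv.origin == "de_novo":
            mother, father = cohort.pedigree.parents_of(cnv.sample)
            for parent in (mother, father):
                assert not any(
                    p.chrom == cnv.chrom and p.start == cnv.start
                    for p in by_sample.get(parent, [])
                )


def test_duo_deletion_genotypes_are_consistent_with_truth(default_cohort):
    """The proband's surviving allele must match the non-deleted parent's
    transmission whenever the genotyped parent is homozygous."""
    cohort = default_cohort
    gt = cohort.genotypes
    checked = 0
    for cnv in cohort.truth.planted_cnvs:
        if cnv.copy != 1 or not cohort.pedigree.is_proband(cnv.sample):
            continue
        mother, father = cohort.pedigree.parents_of(cnv.sample)
        if (mother is None) == (father is None):
            continue
        parent = mother or father
        available_role = "maternal" if mother else "paternal"
        proband_gt = gt.genotypes_in(cnv.sample, cnv.chrom, cnv.start, cnv.end)
        parent_gt = gt.genotypes_in(parent, cnv.chrom, cnv.start, cnv.end)
        assert len(proband_gt) == cohort.config.snp_density
        for pos, allele in proband_gt.items():
            assert len(allele) == 1  # hemizygous single allele
            parent_alleles = set(parent_gt.loc[pos].split("/"))
            if cnv.deleted_haplotype != available_role:
                # surviving haplotype came from the genotyped parent
                assert allele in parent_alleles
        checked += 1
    assert checked > 0


# ---------------------------------------------------------------- round trip


def test_write_read_round_trip(tmp_path):
    cohort = simulate_cohort(small_config())
    manifest = write_cohort(cohort, tmp_path / "out")
    assert manifest["seed"] == cohort.config.seed
    loaded = read_cohort(tmp_path / "out")
    assert np.array_equal(loaded.counts.to_numpy(), cohort.counts.to_numpy())
    assert list(loaded.counts.columns) == list(cohort.counts.columns)
    assert np.array_equal(loaded.expression.to_numpy(),
                          cohort.expression.to_numpy())
    assert np.allclose(loaded.truth.batch_loadings.to_numpy(),
                       cohort.truth.batch_loadings.to_numpy())
    assert loaded.truth.planted_cnvs == cohort.truth.planted_cnvs
    assert loaded.config == cohort.config


def test_truth_file_row_count_matches_generator(tmp_path):
    cohort = simulate_cohort(small_config())
    write_cohort(cohort, tmp_path / "out")
    truth = pd.read_csv(tmp_path / "out" / "truth_cnvs.tsv", sep="\t", comment="#")
    assert len(truth) == len(cohort.truth.planted_cnvs)


def test_write_refuses_nonempty_dir_without_overwrite(tmp_path):
    cohort = simulate_cohort(small_config())
    out = tmp_path / "out"
    write_cohort(cohort, out)
    with pytest.raises(FileExistsError):
        write_cohort(cohort, out)
    write_cohort(cohort, out, overwrite=True)  # explicit overwrite is fine


def test_empty_cohort_round_trips(tmp_path):
    cfg = SimConfig(n_trios=0, n_duos=0, n_singletons=0, n_probes=100,
                    n_genes=10, cnv_probe_span_range=(1, 1), seed=0)
    cohort = simulate_cohort(cfg)
    assert cohort.counts.shape[1] == 0
    manifest = write_cohort(cohort, tmp_path / "empty")
    assert manifest["n_samples"] == 0
    loaded = read_cohort(tmp_path / "empty")
    assert loaded.counts.shape[1] == 0
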