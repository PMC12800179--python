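"""Phantom generation, manipulation ground truth, corpus and split contracts."""

import numpy as np
import pytest
from scipy import ndimage

from affetds._exceptions import (
    NoSurroundingTissueError,
    ParameterError,
    PlacementError,
)
from affetds.synthetic import (
    FEATHER_RADIUS,
    CorpusParams,
    PhantomParams,
    TumorParams,
    build_default_corpus,
    generate_phantom,
    insert_tumor,
    remove_tumor,
    stratified_split,
)

from oracles import disc_area


class TestGeneratePhantom:
    def test_deterministic_under_fixed_seed(self):
        a = generate_phantom(PhantomParams(seed=7))
        b = generate_phantom(PhantomParams(seed=7))
        assert np.array_equal(a.pixels, b.pixels)

    def test_zero_texture_is_piecewise_constant(self):
        sample = generate_phantom(PhantomParams(seed=3, texture_amplitude=0.0))
        assert len(np.unique(sample.pixels)) <= 8

    def test_intensities_in_unit_range(self):
        for seed in (0, 1, 2):
            sample = generate_phantom(PhantomParams(seed=seed, texture_amplitude=0.3))
            assert sample.pixels.min() >= 0.0
            assert sample.pixels.max() <= 1.0

    def test_labelled_real_without_mask(self, phantom224):
        assert phantom224.label == "real"
        assert phantom224.mask is None

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            PhantomParams(size=32)
        with pytest.raises(ParameterError):
            PhantomParams(texture_amplitude=-0.1)


class TestInsertTumor:
    def test_locality_outside_feathered_mask(self, phantom224):
        tumor = TumorParams(center=(120, 100), radii=(10, 12))
        out = insert_tumor(phantom224, tumor, seed=1)
        # the feather kernel has square (Chebyshev) support of FEATHER_RADIUS
        halo = ndimage.binary_dilation(
            out.mask, structure=np.ones((3, 3), dtype=bool), iterations=FEATHER_RADIUS
        )
        assert np.array_equal(out.pixels[~halo], phantom224.pixels[~halo])
        assert (out.pixels[out.mask] != phantom224.pixels[out.mask]).mean() > 0.9

    def test_circular_mask_area_matches_disc_rasterization(self, phantom224):
        tumor = TumorParams(center=(112, 112), radii=(8, 8), boundary_irregularity=0.0)
        out = insert_tumor(phantom224, tumor, seed=0)
        area = int(out.mask.sum())
        ideal = disc_area(8.0)
        assert 0.8 * np.pi * 64 <= area <= 1.2 * np.pi * 64
        assert abs(area - ideal) <= 0.1 * ideal

    def test_output_range_clipped(self, phantom224):
        tumor = TumorParams(center=(112, 112), radii=(14, 14), intensity_offset=0.9)
        out = insert_tumor(phantom224, tumor, seed=0)
        assert out.pixels.max() <= 1.0

    def test_label_and_provenance(self, phantom224):
        out = insert_tumor(phantom224, TumorParams(center=(112, 112)), seed=0)
        assert out.label == "manipulated"
        assert out.provenance == "inserted"

    def test_placement_outside_head_rejected(self, phantom224):
        with pytest.raises(PlacementError):
            insert_tumor(phantom224, TumorParams(center=(10, 10), radii=(6, 6)), seed=0)

    def test_requires_genuine_input(self, phantom224):
        fake = insert_tumor(phantom224, TumorParams(center=(112, 112)), seed=0)
        with pytest.raises(ParameterError):
            insert_tumor(fake, TumorParams(center=(112, 112)), seed=0)


class TestRemoveTumor:
    def _region(self, shape, center=(120, 100), r=9):
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= r * r

    def test_region_statistics_match_ring(self, phantom224):
        mask = self._region(phantom224.pixels.shape)
        out = remove_tumor(phantom224, mask, seed=4)
        ring = ndimage.binary_dilation(mask, iterations=5) & ~mask
        region = out.pixels[mask]
        assert abs(region.mean() - out.pixels[ring].mean()) <= 0.02
        assert abs(region.std() - out.pixels[ring].std()) <= 0.02

    def test_pixels_outside_region_untouched(self, phantom224):
        mask = self._region(phantom224.pixels.shape)
        out = remove_tumor(phantom224, mask, seed=4)
        assert np.array_equal(out.pixels[~mask], phantom224.pixels[~mask])

    def test_constant_image_refilled_with_constant(self):
        from affetds.data import ImageSample

        flat = ImageSample("flat", np.full((64, 64), 0.5), "real")
        mask = self._region((64, 64), center=(32, 32), r=6)
        out = remove_tumor(flat, mask, seed=0)
        assert np.all(out.pixels == 0.5)

    def test_full_mask_signals_no_surrounding_tissue(self, phantom224):
        with pytest.raises(NoSurroundingTissueError):
            remove_tumor(phantom224, np.ones_like(phantom224.pixels, dtype=bool), seed=0)

    def test_empty_mask_rejected(self, phantom224):
        with pytest.raises(ParameterError):
            remove_tumor(phantom224, np.zeros_like(phantom224.pixels, dtype=bool), seed=0)


class TestCorpus:
    def test_default_composition(self):
        n_real, n_ins, n_rem = CorpusParams().counts()
        assert n_real == 774
        assert n_real + n_ins + n_rem == 1378
        assert n_ins >= n_rem  # remainder goes to insertion

    def test_scaled_composition_preserves_ratio(self):
        n_real, n_ins, n_rem = CorpusParams(n_total=10).counts()
        assert n_real == 6
        assert n_ins + n_rem == 4

    def test_small_corpus_reproducible(self, tiny_corpus):
        again = stratified_split(build_default_corpus(seed=3, params=CorpusParams(n_total=40)), seed=3)
        assert [r.id for r in again.records] == [r.id for r in tiny_corpus.records]
        for rid, sample in tiny_corpus.samples.items():
            assert np.array_equal(sample.pixels, again.samples[rid].pixels)

    def test_manipulated_samples_have_masks(self, tiny_corpus):
        for record in tiny_corpus.records:
            sample = tiny_corpus.samples[record.id]
            if record.label == "manipulated":
                assert sample.mask is not None and sample.mask.any()
            else:
                assert sample.mask is None

    def test_materialized_corpus_round_trips(self, tmp_path):
        from affetds.data import DatasetManifest

        manifest = build_default_corpus(seed=5, params=CorpusParams(n_total=10), out_dir=tmp_path)
        loaded = DatasetManifest.load(tmp_path / "manifest.csv")
        assert len(loaded) == 10
        for record in loaded.records:
            assert (tmp_path / record.path).exists()
            sample = loaded.load_sample(record, root=tmp_path)
            # 8-bit PNG quantization: within half a gray level
            assert np.allclose(sample.pixels, manifest.samples[record.id].pixels, atol=0.5 / 255 + 1e-9)


class TestStratifiedSplit:
    def test_full_scale_split_sizes(self):
        # 0.15 * 774 = 116.1 -> 116; 0.15 * 604 = 90.6 -> 91 per split
        from affetds.data import DatasetManifest, ManifestRecord

        records = [ManifestRecord(f"r{i}", "", "real") for i in range(774)]
        records += [ManifestRecord(f"m{i}", "", "manipulated") for i in range(604)]
        split = stratified_split(DatasetManifest(records=records), seed=0)
        sizes = {s: sum(r.split == s for r in split.records) for s in ("train", "val", "test")}
        assert sizes == {"train": 964, "val": 207, "test": 207}

    def test_split_is_a_partition(self, tiny_corpus):
        assigned = [r.split for r in tiny_corpus.records]
        assert all(s in ("train", "val", "test") for s in assigned)
        assert len(tiny_corpus.records) == len({r.id for r in tiny_corpus.records})

    def test_class_ratio_preserved_within_one_sample(self):
        from affetds.data import DatasetManifest, ManifestRecord

        records = [ManifestRecord(f"r{i}", "", "real") for i in range(10)]
        records += [ManifestRecord(f"m{i}", "", "manipulated") for i in range(10)]
        split = stratified_split(DatasetManifest(records=records), seed=1)
        for name in ("train", "val", "test"):
            counts = split.class_counts(name)
            assert abs(counts["real"] - counts["manipulated"]) <= 1

    def test_bad_fractions_rejected(self, tiny_corpus):
        with pytest.raises(ParameterError):
            stratified_split(tiny_corpus, fractions=(0.5, 0.3, 0.3), seed=0)

    def test_deterministic_assignment(self, tiny_corpus):
        a = stratified_split(tiny_corpus, seed=9)
        b = stratified_split(tiny_corpus, seed=9)
        assert [r.split for r in a.records] == [r.split for r in b.records]
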