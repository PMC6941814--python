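"""Activation alignment, PPM construction, information content and logos."""

import numpy as np
import pytest

from motifcnn.architectures import build_model, make_variant
from motifcnn.interpret import (FilterPPM, build_ppm, export_meme,
                                information_content, max_possible_activation,
                                render_logo, scan_activations, ActivationScan)
from motifcnn.motifs import load_motifs
from motifcnn.simulate import one_hot_encode


def _neutral_bn(model):
    """Make every batch-norm an identity (eval mode: running stats 0/1)."""
    for layer in model.layers:
        if hasattr(layer, "running_mean"):
            layer.running_mean[:] = 0
            layer.running_var[:] = 1 - layer.eps


def _planted_model(pool, motif_name="CEBPB"):
    """CNN-25 whose filter 0 carries the log-odds of a fixture motif."""
    model = build_model(make_variant("CNN-25"), 200, seed=0)
    _neutral_bn(model)
    m = pool.get(motif_name)
    w = model.layers[0].params["W"]
    w[:] = 0
    lo = np.log2(np.maximum(m.matrix, 1e-3) / 0.25).astype(w.dtype)
    start = (19 - m.width) // 2
    w[0, start:start + m.width, :] = lo
    return model, m, start


class TestInformationContent:
    def test_uniform_column_is_zero_bits(self):
        assert information_content(np.full((1, 4), 0.25))[0] == pytest.approx(0)

    def test_deterministic_column_is_two_bits(self):
        assert information_content(np.array([[1.0, 0, 0, 0]]))[0] == \
            pytest.approx(2.0)

    def test_half_half_column_is_one_bit(self):
        assert information_content(np.array([[0.5, 0.5, 0, 0]]))[0] == \
            pytest.approx(1.0)

    def test_bounded_between_zero_and_two(self, rng):
        p = rng.dirichlet([0.3] * 4, size=50)
        ic = information_content(p)
        assert np.all(ic >= 0) and np.all(ic <= 2 + 1e-12)

    def test_empty_ppm_rejected(self):
        empty = FilterPPM(0, 1, np.zeros((3, 4)), 0, 1.0)
        with pytest.raises(ValueError):
            information_content(empty)


class TestScan:
    def test_exact_filter_finds_planted_site_position(self, pool):
        model, motif, offset = _planted_model(pool)
        site = motif.sample_site(np.random.default_rng(0))
        seq = "A" * 60 + site + "C" * (140 - motif.width)
        X = one_hot_encode(seq)[None]
        scan = scan_activations(model, 1, X)
        # window start = planted start minus the filter's in-window offset
        assert scan.starts[0, 0] == 60 - offset
        assert scan.rf_width == 19

    def test_tie_breaks_to_leftmost(self, pool):
        model, motif, offset = _planted_model(pool)
        consensus = "".join("ACGT"[i] for i in motif.matrix.argmax(axis=1))
        seq = ("T" * 30 + consensus + "T" * 40 + consensus
               + "T" * (130 - 2 * motif.width))
        scan = scan_activations(model, 1, one_hot_encode(seq)[None])
        assert scan.starts[0, 0] == 30 - offset

    def test_refuses_layer_preceded_by_pooling(self, pool, tiny_dataset):
        model = build_model(make_variant("CNN-25"), 200, seed=0)
        with pytest.raises(ValueError, match="pooling"):
            scan_activations(model, 2, tiny_dataset.sequences[:4])

    def test_layer2_receptive_field_of_unpooled_variant(self, pool,
                                                        tiny_dataset):
        model = build_model(make_variant("CNN-1"), 200, seed=0)
        scan = scan_activations(model, 2, tiny_dataset.sequences[:4])
        assert scan.rf_width == 19 + 4  # 19 + (5 - 1)
        assert scan.values.shape == (4, 128)

    def test_out_of_range_layer_rejected(self, pool, tiny_dataset):
        model = build_model(make_variant("CNN-25"), 200, seed=0)
        with pytest.raises(ValueError, match="layer"):
            scan_activations(model, 5, tiny_dataset.sequences[:2])


class TestBuildPPM:
    def _scan_from(self, values, starts, rf=3):
        return ActivationScan(1, np.asarray(values, float),
                              np.asarray(starts), rf)

    def test_identical_subsequences_give_one_hot_columns(self):
        X = np.stack([one_hot_encode("TACGT")] * 3)
        scan = self._scan_from([[1.0], [1.0], [1.0]], [[1], [1], [1]])
        ppm = build_ppm(scan, X)[0]
        assert ppm.n_sites == 3
        np.testing.assert_allclose(
            ppm.matrix, one_hot_encode("ACG").T)

    def test_threshold_one_keeps_unique_maximiser(self):
        X = np.stack([one_hot_encode("AAAAA")] * 3)
        scan = self._scan_from([[0.5], [1.0], [0.8]], [[1], [1], [1]])
        ppm = build_ppm(scan, X, threshold_frac=1.0)[0]
        assert ppm.n_sites == 1

    def test_windows_overrunning_ends_are_dropped(self):
        X = np.stack([one_hot_encode("AAAAA")] * 2)
        scan = self._scan_from([[1.0], [1.0]], [[-1], [3]])
        ppm = build_ppm(scan, X)[0]  # -1 invalid; 3+3 > 5 invalid
        assert ppm.empty

    def test_empty_flag_not_exception(self):
        X = np.stack([one_hot_encode("AAAAA")])
        scan = self._scan_from([[0.0]], [[1]])
        ppm = build_ppm(scan, X)[0]
        assert ppm.empty and ppm.n_sites == 0

    def test_count_additivity_of_disjoint_alignments(self, rng):
        seqs = ["ACGTA", "GGGTA", "TTGCA", "ACCCA"]
        X = np.stack([one_hot_encode(s) for s in seqs])
        sA = self._scan_from([[1], [1], [0], [0]], [[1]] * 4)
        sB = self._scan_from([[0], [0], [1], [1]], [[1]] * 4)
        sU = self._scan_from([[1], [1], [1], [1]], [[1]] * 4)
        pA = build_ppm(sA, X)[0]
        pB = build_ppm(sB, X)[0]
        pU = build_ppm(sU, X)[0]
        merged = (pA.matrix * pA.n_sites + pB.matrix * pB.n_sites) \
            / (pA.n_sites + pB.n_sites)
        np.testing.assert_allclose(pU.matrix, merged)

    def test_bad_threshold_rejected(self):
        X = np.stack([one_hot_encode("AAAAA")])
        scan = self._scan_from([[1.0]], [[1]])
        with pytest.raises(ValueError):
            build_ppm(scan, X, threshold_frac=0.0)

    def test_planted_filter_recovers_motif_ppm(self, pool):
        """End-to-end oracle: log-odds filter over embedding sequences
        yields a PPM correlated with the source motif."""
        model, motif, offset = _planted_model(pool)
        rng = np.random.default_rng(1)
        seqs = []
        for _ in range(150):
            bg = "".join(rng.choice(list("ACGT"), size=200))
            site = motif.sample_site(rng)
            pos = int(rng.integers(30, 150))
            seqs.append(bg[:pos] + site + bg[pos + motif.width:])
        X = np.stack([one_hot_encode(s) for s in seqs])
        scan = scan_activations(model, 1, X)
        ppm = build_ppm(scan, X)[0]
        assert ppm.n_sites > 30
        core = ppm.matrix[offset:offset + motif.width]
        r = [np.corrcoef(core[i], motif.matrix[i])[0, 1]
             for i in range(motif.width)]
        assert np.mean(r) > 0.9

    def test_analytic_ceiling_bounds_observed_activations(self, pool):
        model, motif, _ = _planted_model(pool)
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(20)]
        X = np.stack([one_hot_encode(s) for s in seqs])
        scan = scan_activations(model, 1, X)
        ceil = max_possible_activation(model, 1)
        assert np.all(scan.values.max(axis=0) <= ceil + 1e-4)
        with pytest.raises(ValueError):
            max_possible_activation(model, 2)


class TestExportAndLogos:
    def _ppms(self):
        good = FilterPPM(0, 1, one_hot_encode("ACG").T, 5, 1.0)
        uniform = FilterPPM(1, 1, np.full((3, 4), 0.25), 4, 1.0)
        empty = FilterPPM(2, 1, np.zeros((3, 4)), 0, 1.0)
        return [good, uniform, empty]

    def test_meme_round_trip_skips_empties(self, tmp_path):
        path = tmp_path / "filters.meme"
        n = export_meme(self._ppms(), path)
        assert n == 2
        pool = load_motifs(path, format="meme")
        assert pool.names == ["filter_0", "filter_1"]
        np.testing.assert_allclose(pool.get("filter_0").matrix,
                                   one_hot_encode("ACG").T, atol=1e-6)

    def test_all_empty_is_an_error(self, tmp_path):
        empty = FilterPPM(0, 1, np.zeros((3, 4)), 0, 1.0)
        with pytest.raises(ValueError, match="empty"):
            export_meme([empty], tmp_path / "x.meme")

    def test_logo_rendering_writes_image(self, tmp_path):
        out = tmp_path / "logo.png"
        render_logo(self._ppms()[0], out, title="deterministic")
        assert out.stat().st_size > 0
        render_logo(self._ppms()[1], tmp_path / "uniform.png")

    def test_empty_logo_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            render_logo(self._ppms()[2], tmp_path / "no.png")
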