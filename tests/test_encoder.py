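"""Spatial/spatiotemporal encoding, unbinding, one-shot prototypes."""

import numpy as np
import pytest

import hdseizure.encoder as enc
from hdseizure import (bind, build_item_memory, learn_prototype,
                       learn_prototypes_from_intervals, load_prototype, nhd,
                       random_hvs, save_prototype, spatial_encode,
                       spatiotemporal_encode, unbind_query)
from hdseizure.encoder import _spatial_counts_numpy
from hdseizure.itemmemory import ItemMemory
from hdseizure.symbolize import Recording
from hdseizure.synthdata import SynthConfig, generate

D = 10_000


@pytest.fixture(scope="module")
def im_odd():
    # odd electrode count: spatial bundles have no ties, so no RNG enters
    return build_item_memory(L=3, n_electrodes=5, D=D, seed=3)


class TestSpatialEncode:
    def test_single_electrode_is_pure_binding(self):
        im = build_item_memory(L=3, n_electrodes=1, D=D, seed=0)
        s = spatial_encode([2], im)
        assert np.array_equal(s, bind(im.symbol_vectors[2], im.electrode_vectors[0]))
        label, dist = unbind_query(s, 0, im)
        assert (label, dist) == (2, 0.0)

    def test_three_electrode_composite_decodes_each_channel(self, im_small):
        symbols = [3, 2, 0]
        s = spatial_encode(symbols, im_small, rng=np.random.default_rng(0))
        for elec, sym in enumerate(symbols):
            label, dist = unbind_query(s, elec, im_small)
            assert label == sym
            # residual of a 3-term bundle concentrates near 0.25
            assert 0.15 < dist < 0.35

    def test_composite_quasi_orthogonal_to_electrode_vectors(self):
        """Mean nhd(S, E_i) over 100 seeds stays within 0.02 of 0.5."""
        vals = []
        for seed in range(100):
            im = build_item_memory(L=3, n_electrodes=3, D=2_000, seed=seed)
            s = spatial_encode([1, 2, 3], im, rng=np.random.default_rng(seed))
            vals += [nhd(s, e) for e in im.electrode_vectors]
        assert abs(np.mean(vals) - 0.5) < 0.02

    def test_wide_composite_still_decodes(self, im_clinical):
        """Symbol recovery from a 60-electrode composite: >= 95% of 200 trials."""
        rng = np.random.default_rng(77)
        hits = 0
        for trial in range(200):
            symbols = rng.integers(0, 256, size=60)
            s = spatial_encode(symbols, im_clinical, rng=rng)
            elec = int(rng.integers(0, 60))
            label, _ = unbind_query(s, elec, im_clinical)
            hits += label == symbols[elec]
        assert hits >= 190

    def test_electrode_permutation_equivariance(self, im_odd):
        """Relabeling electrodes together with their vectors leaves S unchanged."""
        symbols = np.array([0, 1, 2, 3, 1])
        perm = np.array([4, 2, 0, 1, 3])
        im_perm = ItemMemory(
            L=im_odd.L, n_electrodes=im_odd.n_electrodes, D=im_odd.D,
            seed=im_odd.seed, symbol_vectors=im_odd.symbol_vectors,
            electrode_vectors=im_odd.electrode_vectors[perm])
        s = spatial_encode(symbols, im_odd)
        s_perm = spatial_encode(symbols[perm], im_perm)
        assert np.array_equal(s, s_perm)

    def test_bad_inputs(self, im_small):
        with pytest.raises(ValueError):
            spatial_encode([0, 1], im_small)  # wrong electrode count
        with pytest.raises(ValueError):
            spatial_encode([0, 1, 99], im_small)  # unknown symbol
        with pytest.raises(ValueError):
            unbind_query(im_small.symbol_vectors[0], 7, im_small)


class TestSpatioTemporal:
    def test_single_column_equals_spatial(self, im_odd):
        col = np.array([1, 0, 3, 2, 1])
        st = spatiotemporal_encode(col[:, None], im_odd)
        assert np.array_equal(st, spatial_encode(col, im_odd))

    def test_fifteen_columns_one_vector(self, im_small, rng):
        window = rng.integers(0, 4, size=(3, 15))
        st = spatiotemporal_encode(window, im_small, rng=np.random.default_rng(1))
        assert st.shape == (D,) and set(np.unique(st)) <= {0, 1}

    def test_st_similar_to_constituents(self, im_odd, rng):
        """ST of a stationary pattern is closer to each S_t than to fresh
        random vectors."""
        window = np.tile(rng.integers(0, 4, size=(5, 3)), 5)  # 15 columns
        st = spatiotemporal_encode(window, im_odd)
        d_const = [nhd(st, spatial_encode(window[:, t], im_odd))
                   for t in range(window.shape[1])]
        d_rand = [nhd(st, v) for v in random_hvs(20, D, rng)]
        assert max(d_const) < min(d_rand)

    def test_empty_window_rejected(self, im_small):
        with pytest.raises(ValueError):
            spatiotemporal_encode(np.empty((3, 0), dtype=int), im_small)

    def test_numba_kernel_matches_numpy_reference(self, im_clinical, rng):
        sym = rng.integers(0, 256, size=(60, 40))
        fast = enc._spatial_counts(im_clinical, sym)
        ref = _spatial_counts_numpy(im_clinical.symbol_vectors,
                                    im_clinical.electrode_vectors, sym)
        assert np.array_equal(fast, ref)


class TestPrototypes:
    def test_single_window_prototype_is_its_st(self, im_odd, rng):
        window = rng.integers(0, 4, size=(5, 9))
        proto = learn_prototype([window], "ictal", im_odd)
        assert proto.n_windows_bundled == 1
        assert np.array_equal(proto.vector, spatiotemporal_encode(window, im_odd))

    def test_empty_window_list_rejected(self, im_odd):
        with pytest.raises(ValueError):
            learn_prototype([], "ictal", im_odd)

    def test_learning_is_single_pass(self, im_odd, rng, monkeypatch):
        """One-shot: exactly one encode per window, no iteration."""
        calls = {"n": 0}
        original = enc.spatiotemporal_encode

        def counting(*args, **kwargs):
            calls["n"] += 1
            return original(*args, **kwargs)

        monkeypatch.setattr(enc, "spatiotemporal_encode", counting)
        windows = [rng.integers(0, 4, size=(5, 9)) for _ in range(7)]
        proto = learn_prototype(windows, "interictal", im_odd,
                                rng=np.random.default_rng(0))
        assert proto.n_windows_bundled == 7
        assert calls["n"] == 7

    def test_thirty_second_reference_bundles_thirty_windows(self):
        """30 s references at 1 s non-overlapping windows -> k = 30."""
        cfg = SynthConfig(duration_s=70.0, n_channels=6, fs=64.0,
                          seizures=((35.0, 66.0),), seed=5)
        rec, _ = generate(cfg)
        im = build_item_memory(L=9, n_electrodes=6, D=1_000, seed=2)
        p_int, p_ict = learn_prototypes_from_intervals(
            rec, im, interictal_ref=(2.0, 32.0), ictal_ref=(35.0, 65.0),
            window_s=1.0, tie_seed=4)
        assert p_int.n_windows_bundled == 30
        assert p_ict.n_windows_bundled == 30
        assert p_int.state_label == "interictal" and p_ict.state_label == "ictal"

    def test_heldout_ictal_window_is_closer_than_other_prototype(self, e2e):
        """nhd(P_int, P_ict) exceeds the distance from a held-out ictal ST
        to P_ict: the ictal prototype generalizes across noise seeds."""
        ictal = Recording(e2e.test_rec.samples[:, 25 * 512:29 * 512], fs=512)
        from hdseizure import encode_recording
        _, sts = encode_recording(ictal, e2e.im, tie_seed=9)
        d_heldout = float((sts[0] != e2e.p_ict.vector).mean())
        assert nhd(e2e.p_int.vector, e2e.p_ict.vector) > d_heldout

    def test_serialization_round_trip(self, tmp_path, im_odd, rng):
        window = rng.integers(0, 4, size=(5, 9))
        proto = learn_prototype([window], "ictal", im_odd,
                                fingerprint={"D": D, "L": 3})
        path = tmp_path / "p.hdp"
        save_prototype(proto, path)
        again = load_prototype(path)
        assert np.array_equal(again.vector, proto.vector)
        assert again.state_label == "ictal"
        assert again.fingerprint == {"D": D, "L": 3}

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "bogus.hdp"
        path.write_bytes(b"not a prototype file at all")
        with pytest.raises(ValueError, match="magic"):
            load_prototype(path)
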