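"""Frame descriptors: 2D RDF, H-bond counting, order parameter, density."""

import math

import numpy as np
import pytest

from monolayer import synthetic as syn
from monolayer.traj import (
    Frame,
    U_PER_NM3_TO_KG_M3,
    density_profile,
    hbond_count,
    minimal_image,
    order_parameter,
    rdf_2d,
)


def brute_force_rdf(frames, reference, target, r_max, bin_width):
    """O(N²) loop oracle with the same bins and normalization."""
    edges = np.arange(0.0, r_max + bin_width / 2, bin_width)
    hist = np.zeros(edges.size - 1)
    ideal = np.zeros_like(hist)
    for fr in frames:
        ref = fr.centers_of_mass(reference)
        tgt = fr.centers_of_mass(target)
        same = reference == target
        for i in range(ref.shape[0]):
            for j in range(tgt.shape[0]):
                if same and i == j:
                    continue
                dx = tgt[j, 0] - ref[i, 0]
                dy = tgt[j, 1] - ref[i, 1]
                dx -= fr.box[0] * round(dx / fr.box[0])
                dy -= fr.box[1] * round(dy / fr.box[1])
                r = math.hypot(dx, dy)
                # same edge convention as np.histogram (right-open bins,
                # closed last bin)
                if r == edges[-1]:
                    k = hist.size - 1
                else:
                    k = int(np.searchsorted(edges, r, side="right")) - 1
                if 0 <= k < hist.size:
                    hist[k] += 1
        rho = (tgt.shape[0] - (1 if same else 0)) / (fr.box[0] * fr.box[1])
        ideal += ref.shape[0] * rho * np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    return np.where(ideal > 0, hist / ideal, 0.0)


def brute_force_hbonds(frame, d_cut=0.35, angle_cut=30.0):
    """Triple-loop oracle over donors × acceptors with the H–D–A angle."""
    count = 0
    for d, h in frame.donors():
        for a in frame.acceptors():
            if a == d:
                continue
            da = minimal_image(frame.positions[a] - frame.positions[d], frame.box)
            if np.linalg.norm(da) >= d_cut:
                continue
            dh = minimal_image(frame.positions[h] - frame.positions[d], frame.box)
            cosang = (da @ dh) / (np.linalg.norm(da) * np.linalg.norm(dh))
            if math.degrees(math.acos(np.clip(cosang, -1, 1))) < angle_cut:
                count += 1
    return count


def random_gas_frame(rng, n_donor=20, n_acceptor=20, box=(4.0, 4.0, 8.0)):
    """Random donor/acceptor gas with random O–H orientations."""
    pos, names, mids, types = [], [], [], []
    mid = 0
    for _ in range(n_donor):
        d = rng.uniform(0, box, size=3) * [1, 1, 0.5]
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        pos += [d, d + 0.1 * u]
        names += ["OD1", "HD1"]
        mids += [mid, mid]
        types += ["DON", "DON"]
        mid += 1
    for _ in range(n_acceptor):
        pos.append(rng.uniform(0, box, size=3) * [1, 1, 0.5])
        names.append("OA1")
        mids.append(mid)
        types.append("ACC")
        mid += 1
    return Frame(
        positions=np.array(pos),
        box=np.array(box),
        mol_ids=np.array(mids),
        mol_types=np.array(types, dtype=object),
        atom_names=np.array(names, dtype=object),
    )


class TestRDF2D:
    def test_uniform_gas_is_unity(self, point_frame_factory):
        rng = np.random.default_rng(1)
        frames = [
            point_frame_factory(rng.uniform(0, 8, size=(500, 2))) for _ in range(8)
        ]
        res = rdf_2d(frames, "X", "X", r_max=3.0, bin_width=0.1)
        far = res.r > 0.5
        np.testing.assert_allclose(res.g[far], 1.0, atol=0.05)

    def test_ring_spike_matches_oracle(self, point_frame_factory):
        # points on a ring of radius 0.5 around a center: all center–point
        # distances exactly 1.0... use center + 8 points at distance 1.0
        angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        xy = np.vstack([[4.0, 4.0], 4.0 + np.column_stack([np.cos(angles), np.sin(angles)])])
        frames = [point_frame_factory(xy)]
        res = rdf_2d(frames, "X", "X", r_max=2.0, bin_width=0.05)
        oracle = brute_force_rdf(frames, "X", "X", 2.0, 0.05)
        np.testing.assert_allclose(res.g, oracle, rtol=1e-12, atol=1e-12)
        # the 16 exact center–ring separations spike the bin holding r = 1.0
        k = np.argmin(np.abs(res.r - 1.0))
        assert res.g[max(k - 1, 0) : k + 2].max() > 1

    def test_clustered_drugs_peak_at_programmed_spacing(self):
        frames = syn.gen_frames(
            syn.FrameParams(
                lipid_counts={"DPPC": 4},
                drug_counts={"EPI": 12},
                cluster_size=2,
                cluster_spacing=0.4,
                n_frames=3,
            )
        )
        res = rdf_2d(frames, "EPI", "EPI", r_max=2.0, bin_width=0.05)
        assert res.g.max() > 1.0
        assert abs(res.r[np.argmax(res.g)] - 0.4) <= 0.05

    def test_oracle_equivalence_random_configs(self, point_frame_factory):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            frames = [point_frame_factory(rng.uniform(0, 8, size=(60, 2)))]
            got = rdf_2d(frames, "X", "X", r_max=2.5, bin_width=0.1).g
            want = brute_force_rdf(frames, "X", "X", 2.5, 0.1)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)

    def test_r_max_beyond_half_box_rejected(self, point_frame_factory):
        frames = [point_frame_factory(np.random.default_rng(0).uniform(0, 8, (10, 2)))]
        with pytest.raises(ValueError):
            rdf_2d(frames, "X", "X", r_max=4.5)

    def test_empty_selection_rejected(self, point_frame_factory):
        frames = [point_frame_factory(np.random.default_rng(0).uniform(0, 8, (10, 2)))]
        with pytest.raises(ValueError):
            rdf_2d(frames, "Y", "X", r_max=2.0)


class TestHBondCount:
    def geometry_frame(self, d_a=0.34, angle=20.0):
        """One donor–acceptor pair at a prescribed distance and H–D–A angle."""
        d = np.array([2.0, 2.0, 2.0])
        a = d + np.array([d_a, 0.0, 0.0])
        rad = math.radians(angle)
        h = d + 0.1 * np.array([math.cos(rad), math.sin(rad), 0.0])
        return Frame(
            positions=np.array([d, h, a]),
            box=np.array([8.0, 8.0, 25.5]),
            mol_ids=np.array([0, 0, 1]),
            mol_types=np.array(["DON", "DON", "ACC"], dtype=object),
            atom_names=np.array(["OD1", "HD1", "OA1"], dtype=object),
        )

    def test_within_both_cutoffs_counted(self):
        assert hbond_count(self.geometry_frame(0.34, 20.0)).count == 1

    def test_distance_failure_not_counted(self):
        assert hbond_count(self.geometry_frame(0.36, 5.0)).count == 0

    def test_angle_failure_not_counted(self):
        assert hbond_count(self.geometry_frame(0.34, 35.0)).count == 0

    def test_random_gas_matches_triple_loop_oracle(self):
        for seed in range(10):
            frame = random_gas_frame(np.random.default_rng(seed))
            assert hbond_count(frame).count == brute_force_hbonds(frame)

    def test_generator_programmed_count(self):
        (frame,) = syn.gen_frames(
            syn.FrameParams(lipid_counts={"DPPC": 4}, n_hbonds=4, n_decoy_pairs=5)
        )
        stats = hbond_count(frame, donor_type="HBPROBE")
        assert stats.count == 4

    def test_hydrogen_without_donor_rejected(self):
        frame = self.geometry_frame()
        frame.atom_names[0] = "OX1"  # orphan the donor hydrogen
        with pytest.raises(ValueError, match="HD1"):
            hbond_count(frame)

    def test_dha_deviation_convention(self):
        # collinear D–H···A: HDA angle 0 and DHA deviation 0 — both count
        frame = self.geometry_frame(0.30, 0.0)
        assert hbond_count(frame, convention="dha").count == 1
        # H pulled far off the D–A axis: deviation from linearity is large
        frame.positions[1] = frame.positions[0] + np.array([0.0, 0.1, 0.0])
        assert hbond_count(frame, convention="dha").count == 0


class TestOrderParameter:
    def test_all_trans_chain_along_normal(self):
        frames = syn.gen_frames(
            syn.FrameParams(lipid_counts={"DPPC": 10}, tilt_deg=0.0)
        )
        prof = order_parameter(frames, "DPPC")
        np.testing.assert_allclose(prof.s_ch, -0.5, atol=1e-12)

    def test_isotropic_orientations_vanish(self):
        frames = syn.gen_frames(
            syn.FrameParams(
                lipid_counts={"DPPC": 320}, tilt_distribution="isotropic",
                n_frames=2, seed=3,
            )
        )
        prof = order_parameter(frames, "DPPC")
        # ~10⁴ C–H samples in total
        assert abs(prof.s_ch.mean()) < 0.02

    def test_programmed_tilt_matches_analytic(self):
        # uniform-azimuth chains at tilt τ: S_CH = −(3cos²τ − 1)/4
        tau = 30.0
        frames = syn.gen_frames(
            syn.FrameParams(lipid_counts={"DPPC": 400}, tilt_deg=tau, n_frames=4, seed=5)
        )
        prof = order_parameter(frames, "DPPC")
        expected = -(3 * math.cos(math.radians(tau)) ** 2 - 1) / 4
        assert prof.s_ch.mean() == pytest.approx(expected, rel=0.01)

    def test_bounded(self):
        frames = syn.gen_frames(
            syn.FrameParams(lipid_counts={"DPPC": 50}, tilt_distribution="isotropic")
        )
        prof = order_parameter(frames, "DPPC")
        assert np.all(prof.s_ch >= -0.5 - 1e-12) and np.all(prof.s_ch <= 1.0 + 1e-12)

    def test_unknown_lipid_rejected(self):
        frames = syn.gen_frames(syn.FrameParams(lipid_counts={"DPPC": 4}))
        with pytest.raises(ValueError):
            order_parameter(frames, "NOPE")


class TestDensityProfile:
    def test_single_particle_closed_form(self):
        frame = Frame(
            positions=np.array([[1.0, 1.0, 5.05]]),
            box=np.array([8.0, 8.0, 25.5]),
            mol_ids=np.array([0]),
            mol_types=np.array(["X"], dtype=object),
            atom_names=np.array(["C1"], dtype=object),
        )
        prof = density_profile([frame], ["X"], bin_width=0.1)
        k = int(5.05 // 0.1)
        expected = 12.011 / (8.0 * 8.0 * 0.1) * U_PER_NM3_TO_KG_M3
        assert prof.densities["X"][k] == pytest.approx(expected, rel=1e-9)
        assert np.count_nonzero(prof.densities["X"]) == 1

    def test_mass_conservation(self):
        frames = syn.gen_frames(syn.FrameParams(drug_counts={"EPI": 6}))
        prof = density_profile(frames, ["DPPC", "EPI"], bin_width=0.3)
        f = frames[0]
        slab = f.box[0] * f.box[1] * prof.bin_width
        for sp in ("DPPC", "EPI"):
            sel = np.array([t == sp for t in f.mol_types])
            total = f.masses[sel].sum() * U_PER_NM3_TO_KG_M3
            assert prof.densities[sp].sum() * slab == pytest.approx(total, rel=1e-9)

    def test_species_separation_preserved(self):
        frames = syn.gen_frames(
            syn.FrameParams(
                drug_counts={"EPI": 6, "PTX": 6},
                drug_z={"EPI": 9.3, "PTX": 11.2},
            )
        )
        prof = density_profile(frames, ["EPI", "PTX"], bin_width=0.2)
        z_epi = prof.z[np.argmax(prof.densities["EPI"])]
        z_ptx = prof.z[np.argmax(prof.densities["PTX"])]
        assert z_epi < z_ptx

    def test_empty_selection_zero_profile(self):
        frames = syn.gen_frames(syn.FrameParams(lipid_counts={"DPPC": 4}))
        prof = density_profile(frames, ["NOPE"], bin_width=0.5)
        assert np.all(prof.densities["NOPE"] == 0)

    def test_bad_bin_rejected(self):
        frames = syn.gen_frames(syn.FrameParams(lipid_counts={"DPPC": 4}))
        with pytest.raises(ValueError):
            density_profile(frames, ["DPPC"], bin_width=0.0)
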