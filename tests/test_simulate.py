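"""Simulator contracts: determinism, spot photometry, matched pairs, studies."""

import dataclasses
import json

import numpy as np
import pytest

import fetseg as fs
from fetseg.simulate import DEFAULT_RANGES, random_script
from fetseg.types import Phase


def small_scene(**kw):
    return fs.SceneParams(image_size=160, **kw)


def bright_region(frame, quantile=99):
    """Proxy for the spot support: brightest percentile inside the mask."""
    total = frame.pixels.astype(int).sum(axis=2)
    return total > np.percentile(total[frame.mask], quantile)


@pytest.mark.parametrize("phase", list(Phase))
def test_render_is_deterministic(phase):
    a = fs.render_frame(small_scene(), phase, rng_seed=11)
    b = fs.render_frame(small_scene(), phase, rng_seed=11)
    assert np.array_equal(a.pixels, b.pixels)
    assert np.array_equal(a.mask, b.mask)
    c = fs.render_frame(small_scene(), phase, rng_seed=12)
    assert not np.array_equal(a.pixels, c.pixels)


def test_other_frame_without_spot_is_channel_balanced():
    scene = small_scene(spot_visible=False)
    f = fs.render_frame(scene, Phase.OTHER, rng_seed=1)
    means = f.pixels[f.mask].mean(axis=0)
    assert abs(means[1] - means[2]) / max(means[1], means[2]) < 0.05


def test_ablation_spot_blue_dominates_green():
    f = fs.render_frame(small_scene(), Phase.ABLATION, rng_seed=1)
    spot = bright_region(f)
    assert f.pixels[..., 2][spot].max() > f.pixels[..., 1][spot].max()


def test_colour_separation_over_random_scenes():
    """mean(blue - green) within the spot is positive for every ablation
    frame and negative for every targeting frame, across 100 scenes drawn
    from the generator's default variability."""
    rng = np.random.default_rng(7)
    r = DEFAULT_RANGES
    for i in range(100):
        scene = small_scene(
            light_intensity=float(rng.uniform(*r.light_intensity)),
            turbidity=float(rng.uniform(*r.turbidity)),
            spot_strength=float(rng.uniform(*r.spot_strength)),
            tool_angle_deg=float(rng.uniform(0, 360)),
            texture_seed=i,
        )
        phase = Phase.ABLATION if i % 2 else Phase.TARGETING
        f = fs.render_frame(scene, phase, rng_seed=i)
        spot = bright_region(f)
        diff = (f.pixels[..., 2].astype(int) - f.pixels[..., 1].astype(int))[spot]
        if phase is Phase.ABLATION:
            assert diff.mean() > 0
        else:
            assert diff.mean() < 0


def test_mask_conservation():
    for phase in Phase:
        f = fs.render_frame(small_scene(occluder_present=True), phase, rng_seed=3)
        assert f.pixels[~f.mask].sum() == 0


def test_scene_validation_errors():
    with pytest.raises(ValueError):
        fs.render_frame(fs.SceneParams(image_size=-4), Phase.OTHER, 0)
    with pytest.raises(ValueError):
        fs.render_frame(small_scene(scope_radius_frac=1.5), Phase.OTHER, 0)
    with pytest.raises(ValueError):
        fs.render_frame(small_scene(tool_angle_deg=400.0), Phase.OTHER, 0)


class TestMatchedPairs:
    def test_swap_maps_targeting_to_ablation_exactly(self):
        scene = small_scene(background_gray=True)
        ft, fa = fs.render_matched_pair(scene, rng_seed=7)
        assert np.array_equal(fs.swap_green_blue(ft).pixels, fa.pixels)
        assert np.array_equal(fs.swap_green_blue(fa).pixels, ft.pixels)
        assert ft.label is Phase.TARGETING and fa.label is Phase.ABLATION

    def test_pairs_differ_across_seeds(self):
        scene = small_scene(background_gray=True)
        t1, _ = fs.render_matched_pair(scene, rng_seed=7)
        t2, _ = fs.render_matched_pair(scene, rng_seed=8)
        assert not np.array_equal(t1.pixels, t2.pixels)

    def test_chromatic_background_is_refused(self):
        with pytest.raises(ValueError, match="background_gray"):
            fs.render_matched_pair(small_scene(background_gray=False), rng_seed=0)

    def test_ablation_member_is_blue_dominant(self):
        _, fa = fs.render_matched_pair(small_scene(background_gray=True), 3)
        spot = bright_region(fa)
        assert fa.pixels[..., 2][spot].max() > fa.pixels[..., 1][spot].max()


class TestProcedures:
    SCRIPT = (
        (Phase.TARGETING, 10),
        (Phase.ABLATION, 5),
        (Phase.TARGETING, 5),
        (Phase.OTHER, 10),
    )

    def test_labels_follow_script(self):
        script = fs.ProcedureScript(self.SCRIPT, small_scene(), seed=5)
        frames = fs.generate_procedure(script, procedure_id="p")
        assert len(frames) == 30
        labels = [f.label for f in frames]
        expected = sum(([p] * n for p, n in self.SCRIPT), [])
        assert labels == expected
        assert [f.index for f in frames] == list(range(30))

    def test_ablation_needs_adjacent_targeting(self):
        bad = fs.ProcedureScript(
            ((Phase.OTHER, 3), (Phase.ABLATION, 3)), small_scene(), seed=0
        )
        with pytest.raises(ValueError, match="adjacent"):
            fs.generate_procedure(bad)
        frames = fs.generate_procedure(bad, allow_nonadjacent=True)
        assert len(frames) == 6

    def test_procedure_determinism(self):
        script = fs.ProcedureScript(self.SCRIPT, small_scene(), seed=9)
        a = fs.generate_procedure(script)
        b = fs.generate_procedure(script)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_segment_needs_at_least_one_frame(self):
        with pytest.raises(ValueError):
            fs.generate_procedure(
                fs.ProcedureScript(((Phase.OTHER, 0),), small_scene(), seed=0)
            )

    def test_random_script_respects_frame_budget(self):
        rng = np.random.default_rng(0)
        script = random_script(rng, 80, small_scene(), seed=1)
        script.validate()
        assert sum(n for _, n in script.segments) == 80


class TestStudy:
    def test_layout_and_manifest(self, tmp_path):
        manifest = fs.generate_study(
            tmp_path / "s", n_procedures=5, seed=42, image_size=96,
            frames_per_procedure=12,
        )
        procs = manifest["procedures"]
        assert len(procs) == 5
        angles = [p["scene"]["tool_angle_deg"] for p in procs.values()]
        assert len(set(angles)) == 5
        for pid in procs:
            assert (tmp_path / "s" / pid / "labels.csv").exists()
            assert (tmp_path / "s" / pid / "frames" / "000000.png").exists()
        # clinical-variability pattern: turbid, dim, weak-spot procedures
        assert procs["proc_02"]["scene"]["turbidity"] == pytest.approx(0.7)
        assert procs["proc_03"]["scene"]["light_intensity"] == pytest.approx(0.25)
        assert procs["proc_04"]["scene"]["spot_strength"] == pytest.approx(0.12)

    def test_single_procedure_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            fs.generate_study(tmp_path / "s", n_procedures=1, seed=0)

    def test_existing_output_needs_overwrite(self, tmp_path):
        root = tmp_path / "s"
        fs.generate_study(root, n_procedures=2, seed=0, image_size=64,
                          frames_per_procedure=8)
        with pytest.raises(FileExistsError):
            fs.generate_study(root, n_procedures=2, seed=0, image_size=64,
                              frames_per_procedure=8)
        fs.generate_study(root, n_procedures=2, seed=0, image_size=64,
                          frames_per_procedure=8, overwrite=True)

    def test_manifest_reproducible(self, tmp_path):
        m1 = fs.generate_study(tmp_path / "a", n_procedures=2, seed=7,
                               image_size=64, frames_per_procedure=8)
        m2 = fs.generate_study(tmp_path / "b", n_procedures=2, seed=7,
                               image_size=64, frames_per_procedure=8)
        assert json.dumps(m1, sort_keys=True) == json.dumps(m2, sort_keys=True)
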