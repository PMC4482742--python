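"""Fascicle geometry, dataset parsing and architecture summaries."""

import math

import numpy as np
import pytest

from hillcalf.architecture3d import (
    ArchitectureSummary,
    Fascicle,
    FascicleFormatError,
    FascicleSet,
    chord_length,
    fascicle_length,
    line_of_action,
    pennation_angle,
    read_fascicle_dataset,
    read_landmarks,
    resample_polyline,
    segmentwise_pennation,
    summarize,
    write_fascicle_dataset,
)
from hillcalf.synthetic_experiments import NoiseModel, generate_fascicle_set


def straight_fascicle(length=10.0, direction=(1, 0, 0), n=20):
    d = np.asarray(direction, float)
    d /= np.linalg.norm(d)
    return Fascicle(points=np.outer(np.linspace(0, length, n), d))


# -- geometry -----------------------------------------------------------------

def test_straight_segment_lengths():
    f = straight_fascicle(10.0)
    assert fascicle_length(f) == pytest.approx(10.0, rel=1e-12)
    assert chord_length(f) == pytest.approx(10.0, rel=1e-12)


def test_semicircle_arc_vs_chord():
    r = 5.0
    theta = np.linspace(0, math.pi, 20)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), np.zeros_like(theta)])
    f = Fascicle(points=pts)
    assert chord_length(f) == pytest.approx(2 * r, rel=1e-12)
    # inscribed polygon arc length: slightly below pi*r, within discretization
    assert fascicle_length(f) == pytest.approx(math.pi * r, rel=0.01)
    assert fascicle_length(f) < math.pi * r


def test_arc_never_below_chord():
    rng = np.random.default_rng(7)
    for _ in range(20):
        pts = rng.normal(size=(20, 3))
        f = Fascicle(points=pts)
        assert fascicle_length(f) >= chord_length(f) - 1e-12


def test_pennation_examples():
    axis = np.array([1.0, 0.0, 0.0])
    assert pennation_angle(straight_fascicle(direction=(1, 0, 0)), axis) == pytest.approx(0.0, abs=1e-9)
    assert pennation_angle(straight_fascicle(direction=(1, 1, 0)), axis) == pytest.approx(45.0, rel=1e-9)
    assert pennation_angle(straight_fascicle(direction=(-1, 0, 0)), axis) == pytest.approx(0.0, abs=1e-9)
    assert segmentwise_pennation(straight_fascicle(direction=(1, 1, 0)), axis) == pytest.approx(45.0)


def test_line_of_action():
    s = FascicleSet(fascicles=[straight_fascicle()],
                    origins=np.array([[0.0, 0.0, 0.0]]),
                    insertions=np.array([[0.0, 0.0, 10.0]]))
    assert line_of_action(s) == pytest.approx([0, 0, 1])
    # translation invariance
    s2 = FascicleSet(fascicles=s.fascicles,
                     origins=s.origins + 5.0, insertions=s.insertions + 5.0)
    assert line_of_action(s2) == pytest.approx([0, 0, 1])
    # two origins are averaged before differencing
    s3 = FascicleSet(fascicles=s.fascicles,
                     origins=np.array([[1.0, 0, 0], [-1.0, 0, 0]]),
                     insertions=np.array([[0.0, 0, 10.0]]))
    assert line_of_action(s3) == pytest.approx([0, 0, 1])


def test_summary_rigid_motion_invariance():
    fs = generate_fascicle_set("bipennate", n_fascicles=60, seed=3,
                               noise=NoiseModel.zero())
    base = summarize(fs)
    # random rotation + translation applied to fascicles and landmarks alike
    rng = np.random.default_rng(0)
    a, b, c = rng.uniform(0, 2 * math.pi, 3)
    rz = np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]])
    ry = np.array([[math.cos(b), 0, math.sin(b)], [0, 1, 0], [-math.sin(b), 0, math.cos(b)]])
    rot = rz @ ry
    shift = rng.normal(size=3) * 30
    moved = FascicleSet(
        fascicles=[Fascicle(points=f.points @ rot.T + shift) for f in fs.fascicles],
        origins=fs.origins @ rot.T + shift, insertions=fs.insertions @ rot.T + shift)
    s2 = summarize(moved)
    assert s2.length_mean == pytest.approx(base.length_mean, rel=1e-9)
    assert s2.pennation_mean == pytest.approx(base.pennation_mean, rel=1e-9)
    assert s2.length_sd == pytest.approx(base.length_sd, rel=1e-9)


def test_single_fascicle_summary_has_zero_sd():
    s = FascicleSet(fascicles=[straight_fascicle()],
                    origins=np.zeros((1, 3)), insertions=np.array([[0, 0, 10.0]]))
    out = summarize(s)
    assert out.count == 1 and out.length_sd == 0.0 and out.pennation_sd == 0.0


def test_resample_changes_arc_little():
    theta = np.linspace(0, 1.0, 41)
    pts = np.column_stack([10 * theta, 0.5 * np.sin(2 * theta), np.zeros_like(theta)])
    arc_41 = Fascicle(points=pts).points
    res = resample_polyline(pts, 20)
    l41 = fascicle_length(Fascicle(points=arc_41))
    l20 = fascicle_length(Fascicle(points=res))
    assert abs(l20 - l41) / l41 < 0.005


# -- synthetic generator ------------------------------------------------------

def test_generator_exact_geometry_without_noise():
    fs = generate_fascicle_set("unipennate", n_fascicles=40, mean_length=14.0,
                               length_sd=0.0, mean_pennation=15.8, pennation_sd=0.0,
                               noise=NoiseModel.zero(), seed=1, sagitta_frac=0.0)
    axis = line_of_action(fs)
    for f in fs.fascicles:
        assert pennation_angle(f, axis) == pytest.approx(15.8, abs=1e-9)
        assert fascicle_length(f) == pytest.approx(14.0, rel=1e-9)


def test_generator_bow_preserves_chord_pennation():
    fs = generate_fascicle_set("unipennate", n_fascicles=20, mean_length=14.0,
                               length_sd=0.0, mean_pennation=12.0, pennation_sd=0.0,
                               noise=NoiseModel.zero(), seed=1)
    axis = line_of_action(fs)
    s = summarize(fs, axis)
    assert s.pennation_mean == pytest.approx(12.0, abs=1e-6)
    for f in fs.fascicles:
        assert fascicle_length(f) > chord_length(f)  # the bow adds arc length


def test_generator_noisy_recovery():
    """Mean measured arc length agrees with the target within noise inflation."""
    fs = generate_fascicle_set("unipennate", n_fascicles=1838, mean_length=14.0,
                               length_sd=2.2, mean_pennation=15.8, pennation_sd=5.4,
                               noise=NoiseModel(digitizer_sd=0.07), seed=11)
    s = summarize(fs)
    # point jitter only inflates a polyline's arc length (E|seg+eps| >= |seg|);
    # bound the inflation by 2*19*sigma^2/segment and allow 3 SE on top
    se = s.length_sd / math.sqrt(s.count)
    inflation = 2 * 19 * 0.07 ** 2 / (14.0 / 19)
    assert 14.0 - 3 * se < s.length_mean < 14.0 + inflation + 3 * se
    assert s.pennation_mean == pytest.approx(15.8, abs=1.0)


def test_generator_determinism():
    a = generate_fascicle_set("bipennate", n_fascicles=25, seed=42)
    b = generate_fascicle_set("bipennate", n_fascicles=25, seed=42)
    for fa, fb in zip(a.fascicles, b.fascicles):
        assert np.array_equal(fa.points, fb.points)


def test_generator_rejects_degenerate():
    with pytest.raises(ValueError):
        generate_fascicle_set("unipennate", n_fascicles=0)
    with pytest.raises(ValueError):
        generate_fascicle_set("tripennate")
    with pytest.raises(ValueError):
        generate_fascicle_set("unipennate", mean_length=-1.0)


# -- text dialect -------------------------------------------------------------

def test_write_read_roundtrip(tmp_path):
    fs = generate_fascicle_set("unipennate", n_fascicles=15, seed=5)
    path = tmp_path / "set.txt"
    write_fascicle_dataset(fs, path)
    back = read_fascicle_dataset(path)
    assert len(back) == 15
    for fa, fb in zip(fs.fascicles, back.fascicles):
        assert np.allclose(fa.points, fb.points, atol=1e-6)


def test_read_fixed_blocks_without_separators(tmp_path):
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(40, 3))
    path = tmp_path / "flat.txt"
    path.write_text("\n".join(f"{x:.4f} {y:.4f} {z:.4f}" for x, y, z in pts))
    fs = read_fascicle_dataset(path)
    assert len(fs) == 2


def test_read_index_column(tmp_path):
    lines = []
    for idx in (1, 2):
        for k in range(20):
            lines.append(f"{idx} {k * 0.5:.2f} 0.0 {idx:.1f}")
    path = tmp_path / "indexed.txt"
    path.write_text("\n".join(lines))
    fs = read_fascicle_dataset(path)
    assert len(fs) == 2
    assert fascicle_length(fs.fascicles[0]) == pytest.approx(9.5)


def test_read_comma_delimited_with_comments(tmp_path):
    block = "\n".join(f"{k * 1.0}, 0.0, 0.0" for k in range(20))
    path = tmp_path / "commas.txt"
    path.write_text("# digitized fascicles\n" + block + "\n\n" + block + "\n")
    fs = read_fascicle_dataset(path)
    assert len(fs) == 2


def test_strict_mode_names_offending_fascicle(tmp_path):
    good = "\n".join(f"{k * 1.0} 0 0" for k in range(20))
    bad = "\n".join(f"{k * 1.0} 1 0" for k in range(19))
    path = tmp_path / "bad.txt"
    path.write_text(good + "\n\n" + bad + "\n")
    with pytest.raises(FascicleFormatError, match="#2"):
        read_fascicle_dataset(path, strict=True)
    lenient = read_fascicle_dataset(path, strict=False)
    assert all(len(f.points) == 20 for f in lenient.fascicles)


def test_unparseable_line_reports_number(tmp_path):
    path = tmp_path / "junk.txt"
    path.write_text("1.0 2.0 3.0\nnot a row\n")
    with pytest.raises(FascicleFormatError, match="line 2"):
        read_fascicle_dataset(path)


def test_read_landmarks(tmp_path):
    path = tmp_path / "marks.txt"
    path.write_text("origin 0 0 0\norigin 2 0 0\ninsertion 1 0 10\n")
    marks = read_landmarks(path)
    assert marks["origin"].shape == (2, 3)
    assert marks["insertion"][0] == pytest.approx([1, 0, 10])
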