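"""Shape language: primitive classes, sinquads, switches, keys."""

import numpy as np
import pytest

from sinquad import (
    Contour,
    Key,
    PrimitiveClass,
    build_sinquads,
    canonicalize_key,
    classify_primitive,
    encode_key,
    generate_circle,
    generate_primitive_fixture,
    generate_rosette,
    generate_vertebra,
    match_equivalence_class,
    parse_key,
    resample_contour,
    segment_primitives,
    VertebraParams,
)
from sinquad.contours import CharVector, open_char_vectors
from sinquad.language import PRIMITIVE_TABLE, merge_short_runs, resolve_quadrants


class TestPrimitiveClassification:
    def test_table_has_sixteen_rows(self):
        assert len(PRIMITIVE_TABLE) == 16
        assert set(PRIMITIVE_TABLE.values()) == {
            (i, j) for i in (1, 2, 3, 4) for j in (1, 2, 3, 4)
        }

    def test_oblique_ascending_line_quadrant_1(self):
        cls = classify_primitive(CharVector("+", "0", "+", "+"))
        assert cls.j == 1 and cls.i == 1

    def test_quadrant_from_increment_signs(self):
        for (sx, sy), j in ((("+", "+"), 1), (("-", "+"), 2),
                            (("-", "-"), 3), (("+", "-"), 4)):
            t = "+" if j in (1, 3) else "-"
            assert classify_primitive(CharVector(t, "0", sx, sy)).j == j

    def test_ideal_s33_arc_classifies_to_p33(self):
        pts = generate_primitive_fixture(PrimitiveClass(3, 3))
        classes = {classify_primitive(c) for c in open_char_vectors(pts)}
        assert classes == {PrimitiveClass(3, 3)}

    def test_variable_curvature_same_sign_pattern_same_class(self):
        # spiral arc in quadrant 1 with tightening curvature: the sign
        # pattern is constant so the class matches the ideal arc's
        th = np.linspace(np.deg2rad(20), np.deg2rad(70), 12)
        r = 60.0 - 25.0 * (th - th[0]) / (th[-1] - th[0])
        # left-turning arc: tangent angle = th, radius varies
        pts = [np.zeros(2)]
        for k in range(1, len(th)):
            step = 0.5 * (r[k - 1] + r[k]) * (th[k] - th[k - 1])
            d = np.array([np.cos(th[k - 1]), np.sin(th[k - 1])])
            pts.append(pts[-1] + step * d)
        classes = {classify_primitive(c) for c in open_char_vectors(np.array(pts))}
        assert classes == {PrimitiveClass(2, 1)}

    def test_invalid_indices_rejected(self):
        with pytest.raises(ValueError):
            PrimitiveClass(0, 1)
        with pytest.raises(ValueError):
            PrimitiveClass(1, 5)


class TestSegmentation:
    def test_circle_four_sinquads_in_ccw_order(self):
        res = resample_contour(generate_circle(), 5.0)
        prims = segment_primitives(res)
        sinquads, switches = build_sinquads(prims, res)
        assert len(sinquads) == 4
        assert len(switches) == 4
        quads = [s.quadrant for s in sinquads]
        k = quads.index(1)
        assert quads[k:] + quads[:k] == [1, 2, 3, 4]

    def test_partition_conservation(self):
        for contour in (generate_circle(), generate_rosette(),
                        generate_vertebra(VertebraParams(lesion_severity=0.5))):
            res = resample_contour(contour, 5.0)
            prims = segment_primitives(res)
            assert sum(p.length for p in prims) == len(res)
            covered = sorted(i for p in prims for i in p.indices(len(res)))
            assert covered == list(range(len(res)))

    def test_rosette_has_twelve_sinquads(self):
        res = resample_contour(generate_rosette(), 5.0)
        prims = segment_primitives(res)
        sinquads, switches = build_sinquads(prims, res)
        assert len(sinquads) == 12
        assert len(switches) == 12

    def test_consecutive_sinquads_differ_in_quadrant(self):
        res = resample_contour(generate_rosette(), 5.0)
        sinquads, _ = build_sinquads(segment_primitives(res), res)
        quads = [s.quadrant for s in sinquads]
        for a, b in zip(quads, quads[1:] + quads[:1]):
            assert a != b

    def test_resolve_quadrants_look_behind(self):
        chars = [
            CharVector("+", "0", "+", "+"),   # q1
            CharVector("V", "V", "0", "+"),   # axis: inherits q1
            CharVector("-", "0", "-", "+"),   # q2
        ]
        assert resolve_quadrants(chars) == [1, 1, 2]

    def test_merge_short_runs_prefers_same_quadrant(self):
        labels = ["a1", "a1", "a1", "b1", "c2", "c2", "c2"]
        prefer = {"a1": 1, "b1": 1, "c2": 2}
        merged = merge_short_runs(labels, 2, prefer)
        assert merged == ["a1", "a1", "a1", "a1", "c2", "c2", "c2"]

    def test_merge_min_one_is_noop(self):
        labels = ["a", "b", "a"]
        assert merge_short_runs(labels, 1) == labels


class TestConvexityAndKeys:
    def test_convex_contour_all_bits_one(self):
        for contour in (generate_circle(),):
            key = canonicalize_key(_encode(contour))
            assert all(tok[2] == "1" for tok in key.tokens)

    def test_rosette_convexity_pattern(self):
        key = canonicalize_key(_encode(generate_rosette()))
        assert [t[2] for t in key.tokens] == list("101101101101")

    def test_key_chaining(self):
        for contour in (generate_circle(), generate_rosette(),
                        generate_vertebra(VertebraParams(lesion_severity=0.9))):
            key = _encode(contour)
            toks = key.tokens
            for a, b in zip(toks, toks[1:] + toks[:1]):
                assert a[1] == b[0]

    def test_parse_and_roundtrip(self):
        key = parse_key("341.430.341.411")
        assert str(key) == "341.430.341.411"
        assert len(key) == 4

    def test_malformed_tokens_rejected(self):
        for bad in ("", "34", "3411", "451", "342", "331", "abc", "341.", "341..411"):
            with pytest.raises(ValueError):
                parse_key(bad)

    def test_canonicalize_rotates_to_34(self):
        assert str(canonicalize_key(parse_key("411.341"))) == "341.411"
        assert str(canonicalize_key(parse_key("341.411"))) == "341.411"

    def test_canonicalize_without_34_uses_smallest_rotation(self):
        assert str(canonicalize_key(parse_key("231.320"))) == "231.320"
        assert str(canonicalize_key(parse_key("320.231"))) == "231.320"

    def test_match_equivalence_class_table(self):
        assert match_equivalence_class(parse_key("341.411")) == "typical"
        assert match_equivalence_class(parse_key("341.430.341.411")) == "typical"
        for atyp in ("341.430.341.430.341.421.210",
                     "341.430.311.140.411",
                     "341.430.341.430.341.411.121.210"):
            assert match_equivalence_class(atyp) == "atypical"


class TestKeyInvariance:
    def test_translation_and_scaling(self):
        v = generate_vertebra(VertebraParams(lesion_severity=0.5))
        base = str(canonicalize_key(_encode(v)))
        assert str(canonicalize_key(_encode(v.translated(500.0, -250.0)))) == base
        assert str(canonicalize_key(_encode(v.scaled(2.0)))) == base

    def test_rotation_by_360_is_identity(self):
        c = generate_rosette()
        assert str(canonicalize_key(_encode(c.rotated(360.0)))) == \
            str(canonicalize_key(_encode(c)))

    def test_rotation_by_90_permutes_quadrant_digits(self):
        c = generate_circle()
        base = canonicalize_key(_encode(c))
        rotated = canonicalize_key(_encode(c.rotated(90.0)))
        permuted = Key(tuple(
            f"{int(t[0]) % 4 + 1}{int(t[1]) % 4 + 1}{t[2]}" for t in base.tokens
        ))
        assert str(rotated) == str(canonicalize_key(permuted))


def _encode(contour):
    """Full cyclic key with the pipeline's geometric anchoring."""
    from sinquad import encode_contour

    return encode_contour(contour).key
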