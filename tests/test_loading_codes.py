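"""Loading-code semantics: resolution, merging, dropout statistics,
builtin recipes, and the config grammar."""

import numpy as np
import pytest
from scipy import stats

from stackseg.loading_codes import (
    ChannelSpec,
    LoadingCode,
    LoadingCodeError,
    Merge,
    MissingChannelError,
    Random,
    Simple,
    assemble_subimage,
    builtin_codes,
    parse_loading_code,
    resolve_channel,
    serialize_loading_code,
    set_dropout_rates,
)
from stackseg.stack_io import (
    CANONICAL_CHANNELS,
    LOWER_OOF_CHANNELS,
    OOF_CHANNELS,
    UPPER_OOF_CHANNELS,
    HyperStack,
)


def constant_stack(values: dict, shape=(4, 4)) -> HyperStack:
    return HyperStack(channels={n: np.full(shape, v, dtype=np.float32)
                                for n, v in values.items()})


@pytest.fixture()
def abc_stack():
    return constant_stack({"cyto": 0.2, "mem": 0.6, "mito": 0.9, "bf0": 0.5})


class TestResolve:
    def test_simple_is_bit_identical(self, positive_stack):
        stack, _ = positive_stack
        spec = ChannelSpec(Simple("cyto"))
        img, prov = resolve_channel(spec, stack, np.random.default_rng(0))
        np.testing.assert_array_equal(img, stack["cyto"])
        assert prov == {"kind": "simple", "channel": "cyto",
                        "channel_dropout": False}

    def test_full_dropout_blanks_any_source(self, abc_stack):
        for src in (Simple("cyto"), Random(("cyto", "mem")),
                    Merge(("cyto", "mem"))):
            spec = ChannelSpec(src, channel_dropout_rate=1.0)
            img, prov = resolve_channel(spec, abc_stack, np.random.default_rng(1))
            assert img.max() == 0.0
            assert prov["channel_dropout"]

    def test_merge_mean_and_dilution(self, abc_stack):
        """Pixelwise mean; a dropped member dims the average (zeros stay in
        the denominator)."""
        spec = ChannelSpec(Merge(("cyto", "mem"), merge_dropout_rate=0.0))
        img, _ = resolve_channel(spec, abc_stack, np.random.default_rng(0))
        np.testing.assert_allclose(img, 0.4, atol=1e-7)

        spec_half = ChannelSpec(Merge(("cyto", "mem"), merge_dropout_rate=0.5))
        seen = set()
        for seed in range(40):
            img, prov = resolve_channel(spec_half, abc_stack,
                                        np.random.default_rng(seed))
            expected = (0.2 * (not prov["dropped"][0])
                        + 0.6 * (not prov["dropped"][1])) / 2.0
            np.testing.assert_allclose(img, expected, atol=1e-7)
            seen.add(tuple(prov["dropped"]))
        assert {(False, True), (True, False)} <= seen  # 0.1 and 0.3 both occur

    def test_merge_renormalize_flag(self, abc_stack):
        spec = ChannelSpec(Merge(("cyto", "mem"), merge_dropout_rate=0.5))
        for seed in range(40):
            img, prov = resolve_channel(spec, abc_stack,
                                        np.random.default_rng(seed),
                                        merge_renormalize=True)
            if prov["dropped"] == [True, False]:
                np.testing.assert_allclose(img, 0.6, atol=1e-7)
            elif prov["dropped"] == [False, True]:
                np.testing.assert_allclose(img, 0.2, atol=1e-7)

    def test_merge_dropout_one_is_all_black(self, abc_stack):
        spec = ChannelSpec(Merge(("cyto", "mem", "mito"), merge_dropout_rate=1.0))
        for seed in range(5):
            img, _ = resolve_channel(spec, abc_stack, np.random.default_rng(seed))
            assert img.max() == 0.0

    def test_merge_order_invariance_exact(self, positive_stack):
        stack, _ = positive_stack
        a = ChannelSpec(Merge(("cyto", "mem", "mito")))
        b = ChannelSpec(Merge(("mito", "cyto", "mem")))
        img_a, _ = resolve_channel(a, stack, np.random.default_rng(0))
        img_b, _ = resolve_channel(b, stack, np.random.default_rng(0))
        np.testing.assert_array_equal(img_a, img_b)

    def test_missing_channel_strict_vs_blank(self, abc_stack):
        spec = ChannelSpec(Simple("bf+5"))
        with pytest.raises(MissingChannelError, match="bf\\+5"):
            resolve_channel(spec, abc_stack, np.random.default_rng(0))
        img, _ = resolve_channel(spec, abc_stack, np.random.default_rng(0),
                                 absence_policy="blank")
        assert img.max() == 0.0

    @pytest.mark.parametrize("rate", [0.1, 0.3, 0.5, 0.9])
    def test_channel_dropout_rate_conformance(self, abc_stack, rate):
        """Empirical blank fraction inside the central 99.9% binomial CI."""
        n = 10_000
        spec = ChannelSpec(Simple("cyto"), channel_dropout_rate=rate)
        rng = np.random.default_rng(123)
        blanks = sum(resolve_channel(spec, abc_stack, rng)[1]["channel_dropout"]
                     for _ in range(n))
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, rate)
        assert lo <= blanks <= hi

    def test_merge_dropout_rate_conformance(self, abc_stack):
        n, rate = 10_000, 0.3
        spec = ChannelSpec(Merge(("cyto", "mem"), merge_dropout_rate=rate))
        rng = np.random.default_rng(5)
        drops = np.zeros(2)
        for _ in range(n):
            _, prov = resolve_channel(spec, abc_stack, rng)
            drops += prov["dropped"]
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, rate)
        assert (lo <= drops).all() and (drops <= hi).all()

    def test_random_choice_uniform(self, abc_stack):
        """Chi-square goodness of fit over 10k draws, alpha = 0.001."""
        n = 10_000
        spec = ChannelSpec(Random(("cyto", "mem", "mito")))
        rng = np.random.default_rng(17)
        counts = {"cyto": 0, "mem": 0, "mito": 0}
        for _ in range(n):
            _, prov = resolve_channel(spec, abc_stack, rng)
            counts[prov["channel"]] += 1
        p = stats.chisquare(list(counts.values())).pvalue
        assert p > 0.001


class TestAssemble:
    def test_fluorescence_code_loads_markers_in_order(self, positive_stack):
        stack, _ = positive_stack
        sub = assemble_subimage(stack, builtin_codes()["fluorescence"],
                                np.random.default_rng(0))
        for i, name in enumerate(("cyto", "mem", "mito")):
            np.testing.assert_array_equal(sub.pixels[i], stack[name])

    def test_rand_br_ab_draws_from_correct_sides(self, positive_stack):
        stack, _ = positive_stack
        code = builtin_codes()["rand_br_ab"]
        rng = np.random.default_rng(0)
        lower_seen, upper_seen = set(), set()
        for _ in range(60):
            sub = assemble_subimage(stack, code, rng)
            assert sub.provenance[0]["channel"] in LOWER_OOF_CHANNELS
            assert sub.provenance[1]["channel"] == "bf0"
            assert sub.provenance[2]["channel"] in UPPER_OOF_CHANNELS
            lower_seen.add(sub.provenance[0]["channel"])
            upper_seen.add(sub.provenance[2]["channel"])
        assert lower_seen == set(LOWER_OOF_CHANNELS)
        assert upper_seen == set(UPPER_OOF_CHANNELS)

    def test_all_black_assembles_to_zero_stack(self, positive_stack):
        stack, _ = positive_stack
        sub = assemble_subimage(stack, builtin_codes()["all_black"],
                                np.random.default_rng(3))
        assert sub.pixels.max() == 0.0

    def test_every_builtin_assembles_on_canonical_stack(self, positive_stack):
        stack, _ = positive_stack
        for name, code in builtin_codes().items():
            sub = assemble_subimage(stack, code, np.random.default_rng(1))
            assert sub.pixels.shape == (3, *stack.shape), name
            assert np.isfinite(sub.pixels).all()
            assert 0.0 <= sub.pixels.min() and sub.pixels.max() <= 1.0

    def test_merge_br_structure(self, positive_stack):
        stack, _ = positive_stack
        code = builtin_codes(merge_dropout=0.0)["merge_br"]
        sub = assemble_subimage(stack, code, np.random.default_rng(0))
        assert sub.provenance[0]["kind"] == "merge"
        assert sub.provenance[0]["members"] == ["cyto", "mem", "mito"]
        assert sub.provenance[1] == {"kind": "simple", "channel": "bf0",
                                     "channel_dropout": False}
        assert sub.provenance[2]["channel"] in OOF_CHANNELS
        expected = (stack["cyto"].astype(np.float64) + stack["mem"]
                    + stack["mito"]) / 3.0
        np.testing.assert_allclose(sub.pixels[0], expected, atol=1e-6)

    def test_single_spec_replicates_one_resolution(self, positive_stack):
        stack, _ = positive_stack
        code = builtin_codes()["cytoplasm"]
        sub = assemble_subimage(stack, code, np.random.default_rng(0))
        np.testing.assert_array_equal(sub.pixels[0], sub.pixels[1])
        np.testing.assert_array_equal(sub.pixels[0], sub.pixels[2])

    def test_single_spec_pad_blank_mode(self, positive_stack):
        stack, _ = positive_stack
        code = LoadingCode((ChannelSpec(Simple("cyto")),), name="c",
                           expand="pad-blank")
        sub = assemble_subimage(stack, code, np.random.default_rng(0))
        np.testing.assert_array_equal(sub.pixels[0], stack["cyto"])
        assert sub.pixels[1].max() == 0.0 and sub.pixels[2].max() == 0.0

    def test_fixed_seed_reproduces_bytes(self, positive_stack):
        stack, _ = positive_stack
        code = builtin_codes(merge_dropout=0.5)["merge_br"]
        a = assemble_subimage(stack, code, np.random.default_rng(9))
        b = assemble_subimage(stack, code, np.random.default_rng(9))
        assert a.pixels.tobytes() == b.pixels.tobytes()
        assert a.provenance == b.provenance


class TestDropoutOverride:
    def test_merge_override(self):
        code = builtin_codes(merge_dropout=0.2)["merge_br"]
        new = set_dropout_rates(code, 0.9, param="merge")
        assert new.specs[0].source.merge_dropout_rate == 0.9
        assert code.specs[0].source.merge_dropout_rate == 0.2  # copy

    def test_channel_override_applies_to_all_specs(self):
        code = builtin_codes()["fluorescence"]
        new = set_dropout_rates(code, 0.4, param="channel")
        assert all(s.channel_dropout_rate == 0.4 for s in new.specs)

    def test_template_without_merge_rejected(self):
        with pytest.raises(LoadingCodeError):
            set_dropout_rates(builtin_codes()["fluorescence"], 0.5, param="merge")


class TestGrammar:
    MERGE_BR_TEXT = """
- {merge: [cyto, mem, mito], merge_dropout: 0.5}
- {simple: bf0}
- {random: [bf+3, bf+5, bf+10]}
"""

    def test_merge_br_example(self):
        code = parse_loading_code(self.MERGE_BR_TEXT, name="merge_br")
        assert isinstance(code.specs[0].source, Merge)
        assert code.specs[0].source.merge_dropout_rate == 0.5
        assert code.specs[1].source == Simple("bf0")
        assert code.specs[2].source == Random(("bf+3", "bf+5", "bf+10"))

    def test_unknown_channel_lists_valid_names(self):
        with pytest.raises(Exception) as err:
            parse_loading_code("- {simple: nucleus}")
        assert "nucleus" in str(err.value)
        assert "cyto" in str(err.value)

    def test_rate_out_of_bounds_rejected(self):
        with pytest.raises(LoadingCodeError):
            parse_loading_code("- {simple: cyto, dropout: 1.5}")

    def test_round_trip_on_random_codes(self):
        """serialize(parse(x)) is a fixed point for 50 random codes."""
        rng = np.random.default_rng(0)

        def random_source():
            kind = rng.integers(3)
            if kind == 0:
                return {"simple": str(rng.choice(CANONICAL_CHANNELS))}
            if kind == 1:
                k = int(rng.integers(1, 4))
                cands = rng.choice(CANONICAL_CHANNELS, size=k, replace=False)
                return {"random": [str(c) for c in cands]}
            k = int(rng.integers(1, 4))
            members = [str(c) for c in
                       rng.choice(CANONICAL_CHANNELS, size=k, replace=False)]
            out = {"merge": members}
            if rng.random() < 0.5:
                out["merge_dropout"] = round(float(rng.random()), 3)
            return out

        for _ in range(50):
            entries = []
            for _ in range(int(rng.integers(1, 4))):
                e = random_source()
                if rng.random() < 0.5:
                    e["dropout"] = round(float(rng.random()), 3)
                entries.append(e)
            code = parse_loading_code(entries)
            normal = serialize_loading_code(code)
            assert serialize_loading_code(parse_loading_code(normal)) == normal

    def test_nested_merge_rejected(self):
        with pytest.raises(LoadingCodeError):
            parse_loading_code("- {merge: [{merge: [cyto, mem]}, mito]}")
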