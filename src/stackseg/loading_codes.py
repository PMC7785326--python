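"""Loading codes: assembling model-specific subimage stacks.

A *loading code* gives per-output-channel instructions for building the
network's 3-channel input from a hyper-labeled stack.  Three source
kinds exist:

* ``Simple(name)`` — load a named channel directly;
* ``Random(candidates)`` — load one candidate uniformly at random;
* ``Merge(members, merge_dropout_rate)`` — pixelwise average of the
  members, where each member is independently replaced by a blank
  (all-zero) channel with probability ``merge_dropout_rate`` before
  averaging.

Every output channel additionally carries a ``channel_dropout_rate``: the
probability that the fully resolved channel is replaced by a blank,
simulating cells whose marker is absent.

Merge dilution semantics: dropped members contribute zeros and the
denominator stays at the full member count, so dropout DIMS the merged
channel rather than renormalizing; ``merge_dropout_rate = 1`` therefore
yields an all-black channel, identical to full channel dropout.  A
``merge_renormalize`` flag switches to averaging over surviving members
only, for comparison.

All randomness flows through an explicit numpy Generator, and dropout is
re-rolled on every resolution, making it an augmentation rather than a
fixed dataset attribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .stack_io import (
    CANONICAL_CHANNELS,
    FLUORESCENCE_CHANNELS,
    LOWER_OOF_CHANNELS,
    OOF_CHANNELS,
    UPPER_OOF_CHANNELS,
    HyperStack,
    UnknownChannelError,
    validate_channel_name,
)


class LoadingCodeError(ValueError):
    pass


class MissingChannelError(LoadingCodeError):
    pass


@dataclass(frozen=True)
class Simple:
    name: str

    def __post_init__(self):
        object.__setattr__(self, "name", validate_channel_name(self.name))

    def referenced(self) -> set[str]:
        return {self.name}


@dataclass(frozen=True)
class Random:
    candidates: tuple[str, ...]

    def __post_init__(self):
        if not self.candidates:
            raise LoadingCodeError("Random source needs at least one candidate")
        object.__setattr__(
            self, "candidates",
            tuple(validate_channel_name(c) for c in self.candidates))

    def referenced(self) -> set[str]:
        return set(self.candidates)


@dataclass(frozen=True)
class Merge:
    members: tuple
    merge_dropout_rate: float = 0.0

    def __post_init__(self):
        if not self.members:
            raise LoadingCodeError("Merge source needs at least one member")
        members = tuple(
            m if isinstance(m, (Simple, Random)) else Simple(m)
            for m in self.members
        )
        object.__setattr__(self, "members", members)
        if not 0.0 <= self.merge_dropout_rate <= 1.0:
            raise LoadingCodeError(
                f"merge_dropout_rate out of [0, 1]: {self.merge_dropout_rate}")

    def referenced(self) -> set[str]:
        out: set[str] = set()
        for m in self.members:
            out |= m.referenced()
        return out


ChannelSource = Simple | Random | Merge


@dataclass(frozen=True)
class ChannelSpec:
    """One output channel: a source plus a channel-dropout probability."""

    source: ChannelSource
    channel_dropout_rate: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.channel_dropout_rate <= 1.0:
            raise LoadingCodeError(
                f"channel_dropout_rate out of [0, 1]: {self.channel_dropout_rate}")

    def referenced(self) -> set[str]:
        return self.source.referenced()


@dataclass(frozen=True)
class LoadingCode:
    """Ordered channel specs forming one model's input recipe.

    A code with a single spec feeding a wider network input is expanded
    per ``expand``: ``"replicate"`` copies the one resolved channel to all
    inputs; ``"pad-blank"`` fills the remaining inputs with blanks.
    """

    specs: tuple[ChannelSpec, ...]
    name: str = ""
    expand: str = "replicate"

    def __post_init__(self):
        if not self.specs:
            raise LoadingCodeError("a LoadingCode needs at least one spec")
        object.__setattr__(self, "specs", tuple(self.specs))
        if self.expand not in ("replicate", "pad-blank"):
            raise LoadingCodeError(f"unknown expand mode {self.expand!r}")

    def referenced(self) -> set[str]:
        out: set[str] = set()
        for s in self.specs:
            out |= s.referenced()
        return out


@dataclass
class SubimageStack:
    """Assembled network input: (C, H, W) float32 in [0, 1] + provenance."""

    pixels: np.ndarray
    provenance: list


def _fetch(stack: HyperStack, name: str, absence_policy: str) -> np.ndarray:
    if name in stack:
        return stack[name]
    if absence_policy == "blank":
        return np.zeros(stack.shape, dtype=np.float32)
    raise MissingChannelError(
        f"channel {name!r} absent from stack {stack.source_id!r} "
        f"(present: {stack.channel_names})")


def resolve_channel(spec: ChannelSpec, stack: HyperStack,
                    rng: np.random.Generator, *,
                    absence_policy: str = "strict",
                    merge_renormalize: bool = False):
    """Resolve one spec to a (H, W) image and a provenance record.

    Draw order is fixed (source resolution first, channel dropout last)
    so a given rng state always yields the same result.
    """
    if absence_policy not in ("strict", "blank"):
        raise LoadingCodeError(f"unknown absence policy {absence_policy!r}")
    src = spec.source
    prov: dict = {}
    if isinstance(src, Simple):
        img = _fetch(stack, src.name, absence_policy)
        prov = {"kind": "simple", "channel": src.name}
    elif isinstance(src, Random):
        pick = src.candidates[int(rng.integers(len(src.candidates)))]
        img = _fetch(stack, pick, absence_policy)
        prov = {"kind": "random", "channel": pick,
                "candidates": list(src.candidates)}
    elif isinstance(src, Merge):
        members = []
        dropped = []
        contributions = []
        for m in src.members:
            if isinstance(m, Random):
                pick = m.candidates[int(rng.integers(len(m.candidates)))]
            else:
                pick = m.name
            drop = bool(rng.random() < src.merge_dropout_rate)
            members.append(pick)
            dropped.append(drop)
            if not drop:
                contributions.append((pick, _fetch(stack, pick, absence_policy)))
        # summation in sorted-name order makes the average exactly
        # invariant to member order
        total = np.zeros(stack.shape, dtype=np.float64)
        for _, img_m in sorted(contributions, key=lambda t: t[0]):
            total += img_m
        survivors = len(contributions)
        denom = survivors if merge_renormalize else len(src.members)
        img = total / denom if denom > 0 else total
        prov = {"kind": "merge", "members": members, "dropped": dropped,
                "renormalized": merge_renormalize}
    else:  # pragma: no cover - dataclass union is closed
        raise LoadingCodeError(f"unknown source type {type(src)!r}")

    blanked = bool(rng.random() < spec.channel_dropout_rate)
    if blanked:
        img = np.zeros(stack.shape, dtype=np.float32)
    prov["channel_dropout"] = blanked
    return np.asarray(img, dtype=np.float32), prov


def assemble_subimage(stack: HyperStack, code: LoadingCode,
                      rng: np.random.Generator, *, n_channels: int = 3,
                      absence_policy: str = "strict",
                      merge_renormalize: bool = False) -> SubimageStack:
    """Assemble a subimage stack, expanding short codes to ``n_channels``."""
    images, prov = [], []
    for spec in code.specs:
        img, p = resolve_channel(spec, stack, rng,
                                 absence_policy=absence_policy,
                                 merge_renormalize=merge_renormalize)
        images.append(img)
        prov.append(p)
    if len(images) < n_channels:
        if len(images) != 1:
            raise LoadingCodeError(
                f"code {code.name!r} has {len(images)} specs; expected 1 or "
                f"{n_channels}")
        if code.expand == "replicate":
            images = images * n_channels
            prov = [dict(prov[0], expanded="replicate") for _ in range(n_channels)]
        else:
            blank = np.zeros(stack.shape, dtype=np.float32)
            images = images + [blank] * (n_channels - 1)
            prov = prov + [{"kind": "blank", "expanded": "pad-blank"}
                           for _ in range(n_channels - 1)]
    elif len(images) > n_channels:
        raise LoadingCodeError(
            f"code {code.name!r} has {len(images)} specs > {n_channels} inputs")
    pixels = np.stack(images).astype(np.float32)
    return SubimageStack(pixels=np.clip(pixels, 0.0, 1.0), provenance=prov)


def set_dropout_rates(code: LoadingCode, rate: float, *,
                      param: str = "merge") -> LoadingCode:
    """Return a copy of ``code`` with its dropout knob set to ``rate``.

    ``param="merge"`` sets merge_dropout_rate on every Merge source (error
    if the code has none); ``param="channel"`` sets channel_dropout_rate on
    every spec.
    """
    if param not in ("merge", "channel"):
        raise LoadingCodeError(f"unknown dropout param {param!r}")
    new_specs = []
    touched = False
    for spec in code.specs:
        if param == "merge":
            if isinstance(spec.source, Merge):
                new_specs.append(replace(
                    spec, source=replace(spec.source, merge_dropout_rate=rate)))
                touched = True
            else:
                new_specs.append(spec)
        else:
            new_specs.append(replace(spec, channel_dropout_rate=rate))
            touched = True
    if not touched:
        raise LoadingCodeError(
            f"code {code.name!r} has no {param}-dropout-bearing spec")
    return replace(code, specs=tuple(new_specs))


def builtin_codes(merge_dropout: float = 0.5,
                  channel_dropout: float = 0.0) -> dict[str, LoadingCode]:
    """The stock model recipes.

    Single-marker codes (``cytoplasm`` …) carry one spec and replicate it
    across the network inputs.  ``merge_br`` combines a merged
    fluorescence channel, the in-focus brightfield, and a random
    out-of-focus brightfield plane.
    """
    S, R, M = Simple, Random, Merge

    def spec(src):
        return ChannelSpec(source=src, channel_dropout_rate=channel_dropout)

    codes = {
        "cytoplasm": LoadingCode((spec(S("cyto")),), name="cytoplasm"),
        "membrane": LoadingCode((spec(S("mem")),), name="membrane"),
        "mitochondria": LoadingCode((spec(S("mito")),), name="mitochondria"),
        "brightfield": LoadingCode((spec(S("bf0")),), name="brightfield"),
        "fluorescence": LoadingCode(
            (spec(S("cyto")), spec(S("mem")), spec(S("mito"))),
            name="fluorescence"),
        "random": LoadingCode(
            tuple(spec(R(CANONICAL_CHANNELS)) for _ in range(3)), name="random"),
        "all_black": LoadingCode(
            tuple(ChannelSpec(source=S("bf0"), channel_dropout_rate=1.0)
                  for _ in range(3)),
            name="all_black"),
        "br_pm3": LoadingCode(
            (spec(S("bf-3")), spec(S("bf0")), spec(S("bf+3"))), name="br_pm3"),
        "br_pm5": LoadingCode(
            (spec(S("bf-5")), spec(S("bf0")), spec(S("bf+5"))), name="br_pm5"),
        "br_pm10": LoadingCode(
            (spec(S("bf-10")), spec(S("bf0")), spec(S("bf+10"))), name="br_pm10"),
        "rand_br_ab": LoadingCode(
            (spec(R(LOWER_OOF_CHANNELS)), spec(S("bf0")),
             spec(R(UPPER_OOF_CHANNELS))),
            name="rand_br_ab"),
        "cyto_br": LoadingCode(
            (spec(S("cyto")), spec(S("bf0")), spec(R(OOF_CHANNELS))),
            name="cyto_br"),
        "mem_br": LoadingCode(
            (spec(S("mem")), spec(S("bf0")), spec(R(OOF_CHANNELS))),
            name="mem_br"),
        "mito_br": LoadingCode(
            (spec(S("mito")), spec(S("bf0")), spec(R(OOF_CHANNELS))),
            name="mito_br"),
        "merge_br": LoadingCode(
            (spec(M(("cyto", "mem", "mito"), merge_dropout_rate=merge_dropout)),
             spec(S("bf0")), spec(R(OOF_CHANNELS))),
            name="merge_br"),
    }
    return codes


# ---------------------------------------------------------------------------
# Config-text grammar: each output channel is one of
#   {simple: NAME}
#   {random: [NAMES]}
#   {merge: [NAMES or {random: [...]}], merge_dropout: R}
# optionally carrying  dropout: R  for channel dropout.
# ---------------------------------------------------------------------------

def _parse_source(entry: dict) -> ChannelSource:
    kinds = [k for k in ("simple", "random", "merge") if k in entry]
    if len(kinds) != 1:
        raise LoadingCodeError(
            f"channel entry must have exactly one of simple/random/merge: {entry}")
    kind = kinds[0]
    if kind == "simple":
        return Simple(str(entry["simple"]))
    if kind == "random":
        cands = entry["random"]
        if not isinstance(cands, (list, tuple)):
            raise LoadingCodeError(f"random candidates must be a list: {entry}")
        return Random(tuple(str(c) for c in cands))
    members = entry["merge"]
    if not isinstance(members, (list, tuple)):
        raise LoadingCodeError(f"merge members must be a list: {entry}")
    parsed = []
    for m in members:
        if isinstance(m, dict):
            sub = _parse_source(m)
            if isinstance(sub, Merge):
                raise LoadingCodeError("nested merges are not supported")
            parsed.append(sub)
        else:
            parsed.append(Simple(str(m)))
    rate = float(entry.get("merge_dropout", 0.0))
    return Merge(tuple(parsed), merge_dropout_rate=rate)


def parse_loading_code(text_or_obj, name: str = "") -> LoadingCode:
    """Parse a loading code from YAML/JSON text or an already-loaded object."""
    if isinstance(text_or_obj, str):
        try:
            obj = yaml.safe_load(text_or_obj)
        except yaml.YAMLError as exc:
            raise LoadingCodeError(f"loading-code syntax error: {exc}") from exc
    else:
        obj = text_or_obj
    if isinstance(obj, dict) and "channels" in obj:
        name = obj.get("name", name)
        obj = obj["channels"]
    if isinstance(obj, dict):
        obj = [obj]
    if not isinstance(obj, list) or not obj:
        raise LoadingCodeError(f"a loading code must be a nonempty list, got {obj!r}")
    specs = []
    for entry in obj:
        if not isinstance(entry, dict):
            raise LoadingCodeError(f"channel entry must be a mapping: {entry!r}")
        rate = float(entry.get("dropout", 0.0))
        specs.append(ChannelSpec(source=_parse_source(entry),
                                 channel_dropout_rate=rate))
    return LoadingCode(tuple(specs), name=name)


def _serialize_source(src: ChannelSource) -> dict:
    if isinstance(src, Simple):
        return {"simple": src.name}
    if isinstance(src, Random):
        return {"random": list(src.candidates)}
    members = [
        m.name if isinstance(m, Simple) else {"random": list(m.candidates)}
        for m in src.members
    ]
    out = {"merge": members}
    if src.merge_dropout_rate:
        out["merge_dropout"] = src.merge_dropout_rate
    return out


def serialize_loading_code(code: LoadingCode) -> list[dict]:
    """Inverse of :func:`parse_loading_code` (normal form)."""
    out = []
    for spec in code.specs:
        entry = _serialize_source(spec.source)
        if spec.channel_dropout_rate:
            entry["dropout"] = spec.channel_dropout_rate
        out.append(entry)
    return out
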