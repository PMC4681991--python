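from __future__ import annotations

import json
import random

import pytest
from hypothesis import strategies as st

from rnfkit.fixtures import make_fixtures
from rnfkit.model import Read, ReadTuple, Segment, encode_lrn

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_world(tmp_path_factory):
    """The deterministic toy world: genomes, reads, pseudo-mapper SAMs."""
    out_dir = tmp_path_factory.mktemp("world")
    manifest = make_fixtures(FIXTURE_SEED, str(out_dir))
    return out_dir, manifest


@pytest.fixture(scope="session")
def world_manifest(fixture_world):
    out_dir, _ = fixture_world
    return json.loads((out_dir / "manifest.json").read_text())


# --- hypothesis strategies -------------------------------------------------

directions = st.sampled_from("FRN")

known_interval = st.tuples(
    st.integers(min_value=1, max_value=100_000),
    st.integers(min_value=0, max_value=500),
).map(lambda lr: (lr[0], lr[0] + lr[1]))

segments = st.one_of(
    st.builds(
        Segment,
        genome_id=st.integers(min_value=0, max_value=9),
        chromosome_id=st.integers(min_value=0, max_value=30),
        direction=directions,
        left=st.just(0),
        right=st.just(0),
    ),
    st.tuples(
        st.integers(min_value=0, max_value=9),
        st.integers(min_value=0, max_value=30),
        directions,
        known_interval,
    ).map(lambda t: Segment(t[0], t[1], t[2], t[3][0], t[3][1])),
)

prefixes = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789-",
    max_size=12,
)

extension_tags = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyz0123456789", min_size=1, max_size=6)
extension_values = st.text(
    alphabet="abcdefghijklmnopqrstuvwxyz0123456789,.;:+-", max_size=10)

read_tuples = st.builds(
    ReadTuple,
    tuple_id=st.integers(min_value=1, max_value=16**6),
    reads=st.lists(
        st.builds(Read, segments=st.lists(segments, min_size=1, max_size=3)),
        min_size=1, max_size=3),
    prefix=prefixes,
    extensions=st.lists(st.tuples(extension_tags, extension_values),
                        max_size=3),
)


# --- plain-random generators (for the 10k-scale sweeps) --------------------

_PREFIX_ALPHABET = ("abcdefghijklmnopqrstuvwxyz"
                    "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789-")


def random_segment(rng: random.Random) -> Segment:
    if rng.random() < 0.15:  # all-unknown placement (contaminant style)
        return Segment(rng.randint(0, 5), 0, "N", 0, 0)
    left = rng.randint(1, 10**6)
    return Segment(
        genome_id=rng.randint(0, 5),
        chromosome_id=rng.randint(0, 30),
        direction=rng.choice("FRN"),
        left=left,
        right=left + rng.randint(0, 400),
    )


def random_read_tuple(rng: random.Random, tuple_id: int) -> ReadTuple:
    reads = [
        Read([random_segment(rng) for _ in range(rng.randint(1, 2))])
        for _ in range(rng.randint(1, 3))
    ]
    prefix = "".join(rng.choice(_PREFIX_ALPHABET)
                     for _ in range(rng.randint(0, 10)))
    extensions = [
        ("".join(rng.choice("abcdefghijklmnopqrstuvwxyz")
                 for _ in range(rng.randint(1, 4))),
         "".join(rng.choice("abcdefghijklmnopqrstuvwxyz0123456789")
                 for _ in range(rng.randint(0, 6))))
        for _ in range(rng.randint(0, 2))
    ]
    return ReadTuple(tuple_id=tuple_id, reads=reads, prefix=prefix,
                     extensions=extensions)


def tuple_with_lrn_length(target: int) -> ReadTuple:
    """Build a tuple whose default-policy LRN has exactly ``target`` chars."""
    base = ReadTuple(1, [Read([Segment(1, 1, "F", 100, 199)])], prefix="")
    pad = target - len(encode_lrn(base))
    if pad < 0:
        raise ValueError(f"target {target} shorter than the minimal name")
    return ReadTuple(1, [Read([Segment(1, 1, "F", 100, 199)])],
                     prefix="a" * pad)
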