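"""Shared test helpers (reconstruct shared arrays in the clear)."""

from mpclasso.runtime import PARTIES
from mpclasso.shamir import ShamirEngine


def open_all(engine: ShamirEngine, arr):
    opened = engine._open_to(arr, PARTIES, "test_open", kind="share")
    return opened["AC"]


def decode_all(engine: ShamirEngine, arr):
    return [engine.field.decode(v, arr.frac) for v in open_all(engine, arr)]
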