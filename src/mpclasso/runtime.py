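"""Three-party protocol runtime: roles, message bus, transcript, reveal ledger.

The two data parties (``AC``, the insurer, and ``EMC``, the hospital) and the
input-less helper (``HELPER``) are simulated in one process.  Every byte that
crosses a party boundary goes through a :class:`Bus`, which records an
append-only :class:`Transcript` of (sender, receiver, label, payload kind,
size).  Deliberately opened values are recorded in a :class:`RevealLedger`;
:func:`audit_transcript` checks both against the leakage policy: the helper
may only ever see digests, ciphertexts it cannot decrypt, secret shares,
statistically masked openings and routing metadata, and the only plaintext
values revealed during a full run are the whitelisted aggregates (intersection
size, step-size statistic, stopping statistics, final weights, goodness-of-fit
sums).

Transports: ``in_process`` passes payloads by reference (deterministic, used
by the test-suite), ``tcp`` moves length-prefixed JSON frames over plaintext
localhost sockets.  TCP mode exists for desk-scale integration testing only
and offers no transport security.
"""

from __future__ import annotations

import json
import random
import secrets
import socket
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable

AC = "AC"
EMC = "EMC"
HELPER = "HELPER"
PARTIES = (AC, EMC, HELPER)
SHAMIR_INDEX = {AC: 1, EMC: 2, HELPER: 3}

#: Payload classification tags attached by protocol code to every message.
PAYLOAD_KINDS = frozenset(
    {
        "public",  # parameters, public keys, counts
        "digest",  # keyed hashes of identifiers
        "ciphertext",  # HE ciphertexts
        "share",  # additive or Shamir shares
        "masked",  # statistically masked openings inside sub-protocols
        "metadata",  # routing / bookkeeping
        "coin_secret",  # coin-toss contributions (data parties only)
        "plaintext_feature",  # never legitimate on the wire; used as negative control
    }
)

#: The only values the protocol ever deliberately reveals.
REVEAL_WHITELIST = frozenset(
    {"k", "eta0_max", "ud_num", "ud_den", "final_w", "r2_num", "r2_den"}
)


class ProtocolAbortError(RuntimeError):
    """A party observed an inconsistent protocol state and aborted."""


class PolicyViolationError(RuntimeError):
    """A reveal was attempted without a ledger label."""


class AuditIncompleteError(RuntimeError):
    """Audit was requested on a transcript of an unfinished run."""


class ConfigurationError(ValueError):
    """Roles or transport were misconfigured."""


@dataclass(frozen=True)
class PartyRole:
    name: str
    holds_data: bool
    shamir_index: int
    he_keypair: Any = None

    def __post_init__(self) -> None:
        if self.name == HELPER and (self.holds_data or self.he_keypair is not None):
            raise ConfigurationError("helper supplies no data and holds no HE secret key")


def default_roles() -> tuple[PartyRole, PartyRole, PartyRole]:
    return (
        PartyRole(AC, True, SHAMIR_INDEX[AC]),
        PartyRole(EMC, True, SHAMIR_INDEX[EMC]),
        PartyRole(HELPER, False, SHAMIR_INDEX[HELPER]),
    )


@dataclass(frozen=True)
class Message:
    seq: int
    sender: str
    receiver: str
    label: str
    kind: str
    nbytes: int


class Transcript:
    """Append-only record of every message; payloads kept only on request."""

    def __init__(self, record_payloads: bool = False):
        self.messages: list[Message] = []
        self.payloads: list[Any] | None = [] if record_payloads else None
        self.complete = False

    def append(self, msg: Message, payload: Any) -> None:
        self.messages.append(msg)
        if self.payloads is not None:
            self.payloads.append(payload)

    def __len__(self) -> int:
        return len(self.messages)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self.messages:
                fh.write(json.dumps(m.__dict__) + "\n")


@dataclass
class RevealEntry:
    label: str
    value: Any
    iteration: int | None = None


class RevealLedger:
    """Ordered record of every value deliberately opened to the parties."""

    def __init__(self) -> None:
        self.entries: list[RevealEntry] = []

    def record(self, label: str | None, value: Any, iteration: int | None = None) -> None:
        if not label:
            raise PolicyViolationError("refusing to reveal a value without a ledger label")
        self.entries.append(RevealEntry(label, value, iteration))

    def labels(self) -> set[str]:
        return {e.label for e in self.entries}

    def to_json(self) -> list[dict]:
        return [e.__dict__ for e in self.entries]


# ---------------------------------------------------------------------------
# payload (de)serialization -- used on the wire and for size accounting
# ---------------------------------------------------------------------------


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, bytes):
        return {"__bytes__": obj.hex()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(o) for o in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def _unjsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        if set(obj) == {"__bytes__"}:
            return bytes.fromhex(obj["__bytes__"])
        return {k: _unjsonable(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_unjsonable(o) for o in obj]
    return obj


def serialize_payload(payload: Any) -> bytes:
    return json.dumps(_jsonable(payload), separators=(",", ":")).encode()


def deserialize_payload(data: bytes) -> Any:
    return _unjsonable(json.loads(data.decode()))


def _approx_size(payload: Any) -> int:
    """Cheap upper-ish estimate of the serialized size, for transcript stats."""
    if isinstance(payload, int):
        return max(1, (payload.bit_length() + 7) // 8)
    if isinstance(payload, bytes):
        return len(payload)
    if isinstance(payload, str):
        return len(payload)
    if isinstance(payload, float):
        return 8
    if isinstance(payload, (list, tuple)):
        return 2 + sum(_approx_size(o) for o in payload)
    if isinstance(payload, dict):
        return 2 + sum(len(str(k)) + _approx_size(v) for k, v in payload.items())
    return 8


# ---------------------------------------------------------------------------
# transports
# ---------------------------------------------------------------------------


class InProcessTransport:
    """Per-(sender, receiver) FIFO queues; payloads pass by reference."""

    def __init__(self) -> None:
        self._queues: dict[tuple[str, str], list[Any]] = {}

    def send(self, sender: str, receiver: str, payload: Any) -> Any:
        self._queues.setdefault((sender, receiver), []).append(payload)
        return payload

    def recv(self, sender: str, receiver: str) -> Any:
        q = self._queues.get((sender, receiver))
        if not q:
            raise ProtocolAbortError(f"no pending message from {sender} to {receiver}")
        return q.pop(0)

    def close(self) -> None:
        pass


class TcpLoopbackTransport:
    """Length-prefixed JSON frames over plaintext localhost TCP sockets.

    WARNING: no TLS, no authentication -- integration testing only.
    """

    def __init__(self) -> None:
        self._socks: dict[tuple[str, str], socket.socket] = {}

    def _pair(self, a: str, b: str) -> socket.socket:
        key = (a, b)
        if key not in self._socks:
            listener = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
            listener.bind(("127.0.0.1", 0))
            listener.listen(1)
            out = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
            out.connect(listener.getsockname())
            inc, _ = listener.accept()
            listener.close()
            self._socks[(a, b)] = out
            self._socks[(b, a)] = inc
        return self._socks[key]

    def send(self, sender: str, receiver: str, payload: Any) -> bytes:
        data = serialize_payload(payload)
        sock = self._pair(sender, receiver)
        sock.sendall(len(data).to_bytes(8, "big") + data)
        return data

    def recv(self, sender: str, receiver: str) -> Any:
        sock = self._pair(receiver, sender)
        raw = self._read_exact(sock, 8)
        return deserialize_payload(self._read_exact(sock, int.from_bytes(raw, "big")))

    @staticmethod
    def _read_exact(sock: socket.socket, count: int) -> bytes:
        chunks = []
        while count:
            chunk = sock.recv(count)
            if not chunk:
                raise ProtocolAbortError("peer closed the connection mid-message")
            chunks.append(chunk)
            count -= len(chunk)
        return b"".join(chunks)

    def close(self) -> None:
        for sock in set(self._socks.values()):
            sock.close()
        self._socks.clear()


class Bus:
    """Routes labelled, kind-tagged payloads between parties and logs them."""

    def __init__(self, transport: str = "in_process", record_payloads: bool = False):
        if transport == "in_process":
            self._transport = InProcessTransport()
            self._wire = False
        elif transport == "tcp":
            self._transport = TcpLoopbackTransport()
            self._wire = True
        else:
            raise ConfigurationError(f"unknown transport {transport!r}")
        self.transport_name = transport
        self.transcript = Transcript(record_payloads=record_payloads)
        self._seq = 0

    def send(self, sender: str, receiver: str, label: str, payload: Any, kind: str) -> None:
        if kind not in PAYLOAD_KINDS:
            raise ConfigurationError(f"unknown payload kind {kind!r}")
        if sender == receiver:
            raise ConfigurationError("a party cannot message itself")
        sent = self._transport.send(sender, receiver, payload)
        nbytes = len(sent) if self._wire else _approx_size(payload)
        self.transcript.append(
            Message(self._seq, sender, receiver, label, kind, nbytes), payload
        )
        self._seq += 1

    def recv(self, sender: str, receiver: str) -> Any:
        return self._transport.recv(sender, receiver)

    def exchange(self, label: str, payloads: dict[str, dict[str, Any]], kind: str) -> dict[str, dict[str, Any]]:
        """Send ``payloads[sender][receiver]`` for all pairs, then collect.

        Returns ``received[receiver][sender]``.  Sends strictly in party order
        so transcripts are deterministic.
        """
        for sender in PARTIES:
            for receiver in PARTIES:
                if sender in payloads and receiver in payloads.get(sender, {}):
                    self.send(sender, receiver, label, payloads[sender][receiver], kind)
        received: dict[str, dict[str, Any]] = {}
        for sender in PARTIES:
            for receiver in PARTIES:
                if sender in payloads and receiver in payloads.get(sender, {}):
                    received.setdefault(receiver, {})[sender] = self.recv(sender, receiver)
        return received

    def close(self) -> None:
        self._transport.close()
        self.transcript.complete = True


class ProtocolContext:
    """Everything a protocol choreography needs: bus, ledger, per-party RNGs.

    With ``seed`` set, every party draws randomness from its own seeded
    ``random.Random`` stream (deterministic test mode, insecure); without a
    seed the streams are backed by the OS CSPRNG.
    """

    def __init__(
        self,
        roles: tuple[PartyRole, ...] | None = None,
        transport: str = "in_process",
        seed: int | None = None,
        record_payloads: bool = False,
    ):
        roles = roles if roles is not None else default_roles()
        if len(roles) != 3 or sorted(r.name for r in roles) != sorted(PARTIES):
            raise ConfigurationError("exactly the roles AC, EMC and HELPER are required")
        if sum(not r.holds_data for r in roles) != 1:
            raise ConfigurationError("exactly one input-less helper is required")
        self.roles = {r.name: r for r in roles}
        self.bus = Bus(transport=transport, record_payloads=record_payloads)
        self.ledger = RevealLedger()
        self.seed = seed
        self._rngs: dict[str, random.Random] = {}
        for i, name in enumerate(PARTIES):
            if seed is None:
                self._rngs[name] = secrets.SystemRandom()
            else:
                self._rngs[name] = random.Random((seed * 7919 + i) % 2**31)

    def rng(self, party: str) -> random.Random:
        return self._rngs[party]

    def close(self) -> None:
        self.bus.close()


def run_protocol(
    protocol_fn: Callable[[ProtocolContext], Any],
    roles: tuple[PartyRole, ...] | None = None,
    transport: str = "in_process",
    seed: int | None = None,
    record_payloads: bool = False,
) -> tuple[Any, Transcript, RevealLedger]:
    """Run a protocol choreography under a fresh context and close it."""
    ctx = ProtocolContext(
        roles=roles, transport=transport, seed=seed, record_payloads=record_payloads
    )
    try:
        result = protocol_fn(ctx)
    finally:
        ctx.close()
    return result, ctx.bus.transcript, ctx.ledger


# ---------------------------------------------------------------------------
# audit
# ---------------------------------------------------------------------------


@dataclass
class AuditPolicy:
    helper: str = HELPER
    data_parties: tuple[str, str] = (AC, EMC)
    helper_forbidden_kinds: frozenset = frozenset({"plaintext_feature", "coin_secret"})
    data_party_forbidden_kinds: frozenset = frozenset({"plaintext_feature"})
    reveal_whitelist: frozenset = REVEAL_WHITELIST


def audit_transcript(
    transcript: Transcript,
    ledger: RevealLedger | None = None,
    policy: AuditPolicy | None = None,
) -> list[str]:
    """Check a finished run against the leakage policy; return violations.

    Empty result means: the helper received only digests, ciphertexts under
    keys it does not hold, shares, masked openings and routing metadata; the
    data parties never received each other's plaintext features; and every
    ledger reveal carries a whitelisted label.
    """
    if not transcript.complete:
        raise AuditIncompleteError("transcript is incomplete; run the protocol to the end")
    policy = policy or AuditPolicy()
    violations: list[str] = []
    for m in transcript.messages:
        if m.kind not in PAYLOAD_KINDS:
            violations.append(f"msg {m.seq}: unknown payload kind {m.kind!r}")
        if m.receiver == policy.helper and m.kind in policy.helper_forbidden_kinds:
            violations.append(
                f"msg {m.seq}: helper received forbidden kind {m.kind!r} ({m.label})"
            )
        if (
            m.sender in policy.data_parties
            and m.receiver in policy.data_parties
            and m.kind in policy.data_party_forbidden_kinds
        ):
            violations.append(
                f"msg {m.seq}: data party {m.receiver} received forbidden kind "
                f"{m.kind!r} from {m.sender} ({m.label})"
            )
    if ledger is not None:
        for e in ledger.entries:
            if e.label not in policy.reveal_whitelist:
                violations.append(f"reveal {e.label!r} not in whitelist")
    return violations
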