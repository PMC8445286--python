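"""Three-party secure inner join with a data-less helper.

The two data parties hide their identifier columns with a jointly keyed hash
(the helper never learns the key, so it cannot brute-force identifiers) and
encrypt their feature columns under their own Paillier keys.  The helper
matches equal digests -- learning only the intersection cardinality ``k`` --
and blinds each matched ciphertext with a uniform additive mask supplied,
encrypted, by the *other* data party.  After decryption each data party holds
one half of a 2-out-of-2 additive sharing (mod the MPC field prime) of every
cell of the joined feature table: the insurer holds ``(alpha - z, s)``, the
hospital ``(z, beta - s)``, where ``alpha``/``beta`` are its own and the other
party's feature encodings and ``s``/``z`` the masks.  Nobody sees the joined
table in the clear.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from . import paillier
from .datasets import PlainDataset
from .fields import FieldParams
from .paillier import HECiphertext, PublicKey
from .runtime import AC, EMC, HELPER, ProtocolAbortError, ProtocolContext


class DuplicateIdentifierError(ValueError):
    pass


@dataclass(frozen=True)
class KeyedHashParams:
    """Joint hashing key of the two data parties; unknown to the helper."""

    joint_random_bits: bytes
    hash_name: str = "sha256"

    def __post_init__(self) -> None:
        if len(self.joint_random_bits) * 8 < 128:
            raise ValueError("joint random string must be at least 128 bits")
        if self.hash_name not in hashlib.algorithms_available:
            raise ValueError(f"unsupported hash {self.hash_name!r}")


@dataclass
class HashedColumnSet:
    """What one data party uploads to the helper: digests + own-key ciphertexts."""

    hashed_ids: list[bytes]
    encrypted_features: list[list[HECiphertext]]  # one list per feature column
    column_names: list[str]
    key_id: str

    def __post_init__(self) -> None:
        for col in self.encrypted_features:
            if len(col) != len(self.hashed_ids):
                raise ValueError("feature column length must match digest count")


@dataclass
class MatchResult:
    """The helper's matching outcome; ``k`` is all it may ever output."""

    k: int
    pairs: list[tuple[int, int]]  # (index into AC's rows, index into EMC's rows)

    def __post_init__(self) -> None:
        if self.k != len(self.pairs):
            raise ValueError("k must equal the number of matched pairs")


@dataclass
class AdditiveShareTable:
    """One party's half of the 2-of-2 additive sharing of the joined table.

    Row ``t`` corresponds to the helper's join order ``t``; columns are the
    insurer's features followed by the hospital's (target last).
    """

    party_role: str
    column_names: list[str]
    rows: list[list[int]]
    field: FieldParams
    target_column: str | None = None

    @property
    def k(self) -> int:
        return len(self.rows)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.rows), len(self.column_names))

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        with open(prefix.with_suffix(".csv"), "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(self.column_names)
            for row in self.rows:
                wr.writerow(row)
        sidecar = {
            "party_role": self.party_role,
            "p": str(self.field.p),
            "f": self.field.f,
            "k": self.k,
            "target_column": self.target_column,
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @staticmethod
    def read(prefix: str | Path, field: FieldParams | None = None) -> "AdditiveShareTable":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        fld = field or FieldParams(p=int(meta["p"]), f=meta["f"])
        with open(prefix.with_suffix(".csv")) as fh:
            rd = csv.reader(fh)
            names = next(rd)
            rows = [[int(v) for v in row] for row in rd]
        return AdditiveShareTable(meta["party_role"], names, rows, fld, meta["target_column"])


def reconstruct_join(table_ac: AdditiveShareTable, table_emc: AdditiveShareTable) -> list[list[float]]:
    """Add the two halves and decode -- test/audit helper, defeats the sharing."""
    fld = table_ac.field
    return [
        [fld.decode((x + y) % fld.p) for x, y in zip(ra, rb)]
        for ra, rb in zip(table_ac.rows, table_emc.rows)
    ]


# ---------------------------------------------------------------------------
# protocol steps
# ---------------------------------------------------------------------------


def coin_toss_random_string(ctx: ProtocolContext, bits: int = 128) -> KeyedHashParams:
    """Both data parties exchange local randomness and XOR it; the helper sees nothing."""
    nbytes = bits // 8
    r_ac = ctx.rng(AC).getrandbits(bits).to_bytes(nbytes, "big")
    r_emc = ctx.rng(EMC).getrandbits(bits).to_bytes(nbytes, "big")
    ctx.bus.send(AC, EMC, "coin_share", r_ac, kind="coin_secret")
    ctx.bus.send(EMC, AC, "coin_share", r_emc, kind="coin_secret")
    got_ac = ctx.bus.recv(EMC, AC)
    got_emc = ctx.bus.recv(AC, EMC)
    joint_ac = bytes(a ^ b for a, b in zip(r_ac, got_ac))
    joint_emc = bytes(a ^ b for a, b in zip(got_emc, r_emc))
    if joint_ac != joint_emc:
        raise ProtocolAbortError("coin toss transcripts disagree")
    return KeyedHashParams(joint_random_bits=joint_ac)


def hide_identifiers(ids: list[str], params: KeyedHashParams) -> list[bytes]:
    """Keyed digests H(joint_random_bits || id); equal ids give equal digests."""
    if len(set(ids)) != len(ids):
        raise DuplicateIdentifierError("identifiers must be unique")
    out = []
    for ident in ids:
        h = hashlib.new(params.hash_name)
        h.update(params.joint_random_bits)
        h.update(ident.encode())
        out.append(h.digest())
    return out


def encrypt_feature_columns(
    ds: PlainDataset,
    own_pk: PublicKey,
    fp: FieldParams,
    params: KeyedHashParams,
    rng,
) -> tuple[HashedColumnSet, list[int]]:
    """Secretly permute rows, hash identifiers, fixed-point encode and encrypt.

    Returns the upload set and the permutation (kept by the party).
    """
    perm = list(range(ds.n))
    rng.shuffle(perm)
    ids = [ds.identifiers[i] for i in perm]
    digests = hide_identifiers(ids, params)
    columns = []
    for j in range(len(ds.column_names)):
        col = []
        for i in perm:
            enc = fp.encode(float(ds.features[i, j]))  # raises on overflow
            col.append(paillier.encrypt(own_pk, enc, rng=rng))
        columns.append(col)
    return HashedColumnSet(digests, columns, list(ds.column_names), own_pk.key_id), perm


def match_hashes(set_a: HashedColumnSet, set_b: HashedColumnSet) -> MatchResult:
    """Runs at the helper: pair equal digests, ordered by the AC-side index."""
    for hs in (set_a.hashed_ids, set_b.hashed_ids):
        if len(set(hs)) != len(hs):
            raise ProtocolAbortError("duplicate digest within one party's upload")
    pos_b = {h: j for j, h in enumerate(set_b.hashed_ids)}
    pairs = [
        (i, pos_b[h]) for i, h in enumerate(set_a.hashed_ids) if h in pos_b
    ]
    return MatchResult(k=len(pairs), pairs=pairs)


def blind_and_route(
    match: MatchResult,
    enc_a: HashedColumnSet,
    enc_b: HashedColumnSet,
    masks_for_a: list[list[HECiphertext]],
    masks_for_b: list[list[HECiphertext]],
    pk_a: PublicKey,
    pk_b: PublicKey,
) -> tuple[list[list[HECiphertext]], list[list[HECiphertext]]]:
    """Runs at the helper: homomorphically blind each matched ciphertext.

    ``masks_for_a[c][t]`` encrypts ``p - z`` under AC's key (z drawn by EMC);
    adding it to ``[alpha]_AC`` yields ``[alpha + p - z]_AC``, which AC
    decrypts and reduces mod p to its additive share ``alpha - z``.  Dual for
    EMC.  Returns (ciphertexts routed to AC, ciphertexts routed to EMC), one
    list per column, one entry per joined row.
    """
    if len(masks_for_a) != len(enc_a.column_names) or any(
        len(col) != match.k for col in masks_for_a
    ):
        raise ProtocolAbortError("mask count does not equal k x feature count")
    if len(masks_for_b) != len(enc_b.column_names) or any(
        len(col) != match.k for col in masks_for_b
    ):
        raise ProtocolAbortError("mask count does not equal k x feature count")
    to_ac = [
        [paillier.add_cipher(pk_a, enc_a.encrypted_features[c][i], masks_for_a[c][t])
         for t, (i, _) in enumerate(match.pairs)]
        for c in range(len(enc_a.column_names))
    ]
    to_emc = [
        [paillier.add_cipher(pk_b, enc_b.encrypted_features[c][j], masks_for_b[c][t])
         for t, (_, j) in enumerate(match.pairs)]
        for c in range(len(enc_b.column_names))
    ]
    return to_ac, to_emc


# ---------------------------------------------------------------------------
# full choreography
# ---------------------------------------------------------------------------


def _send_ciphertext_columns(ctx, sender, receiver, label, cols):
    ctx.bus.send(sender, receiver, label, [[c.value for c in col] for col in cols], kind="ciphertext")


def _recv_ciphertext_columns(ctx, sender, receiver, key_id):
    return [
        [HECiphertext(v, key_id) for v in col] for col in ctx.bus.recv(sender, receiver)
    ]


def secure_inner_join(
    ds_a: PlainDataset,
    ds_b: PlainDataset,
    fp: FieldParams,
    ctx: ProtocolContext,
    he_bits: int = paillier.DEFAULT_KEY_BITS,
) -> tuple[AdditiveShareTable, AdditiveShareTable, int]:
    """Full three-party secure inner join.

    Output tables satisfy, for every cell, ``share_AC + share_EMC mod p ==
    fixed-point encoding of the plaintext joined value``, rows aligned across
    parties by the helper's join order.  Beyond the share tables only the
    intersection cardinality ``k`` is revealed (recorded in the ledger).
    """
    p = fp.p
    # 1. HE keypairs; public keys go to everyone.
    seed = ctx.seed
    kp_a = paillier.keygen(he_bits, seed=None if seed is None else (seed * 13 + 1) % 2**31)
    kp_b = paillier.keygen(he_bits, seed=None if seed is None else (seed * 13 + 2) % 2**31)
    ctx.bus.send(AC, EMC, "he_pubkey", kp_a.public_key.n, kind="public")
    ctx.bus.send(AC, HELPER, "he_pubkey", kp_a.public_key.n, kind="public")
    ctx.bus.send(EMC, AC, "he_pubkey", kp_b.public_key.n, kind="public")
    ctx.bus.send(EMC, HELPER, "he_pubkey", kp_b.public_key.n, kind="public")
    ctx.bus.recv(AC, EMC)
    ctx.bus.recv(EMC, AC)
    pk_a = PublicKey(ctx.bus.recv(AC, HELPER))  # AC's public key as the helper knows it
    pk_b = PublicKey(ctx.bus.recv(EMC, HELPER))

    # 2. joint hashing key (helper excluded).
    params = coin_toss_random_string(ctx)

    # 3-4. permute, hash, encrypt, upload.
    up_a, _ = encrypt_feature_columns(ds_a, kp_a.public_key, fp, params, ctx.rng(AC))
    up_b, _ = encrypt_feature_columns(ds_b, kp_b.public_key, fp, params, ctx.rng(EMC))
    ctx.bus.send(AC, HELPER, "hashed_ids", up_a.hashed_ids, kind="digest")
    ctx.bus.send(EMC, HELPER, "hashed_ids", up_b.hashed_ids, kind="digest")
    _send_ciphertext_columns(ctx, AC, HELPER, "enc_features", up_a.encrypted_features)
    _send_ciphertext_columns(ctx, EMC, HELPER, "enc_features", up_b.encrypted_features)
    helper_a = HashedColumnSet(
        ctx.bus.recv(AC, HELPER),
        _recv_ciphertext_columns(ctx, AC, HELPER, pk_a.key_id),
        list(ds_a.column_names),
        pk_a.key_id,
    )
    helper_b = HashedColumnSet(
        ctx.bus.recv(EMC, HELPER),
        _recv_ciphertext_columns(ctx, EMC, HELPER, pk_b.key_id),
        list(ds_b.column_names),
        pk_b.key_id,
    )

    # 5. match; k is the only output the helper may publish.
    match = match_hashes(helper_a, helper_b)
    ctx.bus.send(HELPER, AC, "k_announce", match.k, kind="public")
    ctx.bus.send(HELPER, EMC, "k_announce", match.k, kind="public")
    k_at_ac = ctx.bus.recv(HELPER, AC)
    k_at_emc = ctx.bus.recv(HELPER, EMC)
    ctx.ledger.record("k", match.k)

    m_a, m_b = len(ds_a.column_names), len(ds_b.column_names)
    joined_names = list(ds_a.column_names) + list(ds_b.column_names)
    target = ds_b.target_column or ds_a.target_column

    # 6-7. masks: each party draws uniform field elements for the OTHER
    # party's columns and encrypts their negation under the other party's key.
    z_masks = [[ctx.rng(EMC).randrange(p) for _ in range(k_at_emc)] for _ in range(m_a)]
    s_masks = [[ctx.rng(AC).randrange(p) for _ in range(k_at_ac)] for _ in range(m_b)]
    enc_z = [[paillier.encrypt(pk_a, p - z, rng=ctx.rng(EMC)) for z in col] for col in z_masks]
    enc_s = [[paillier.encrypt(pk_b, p - s, rng=ctx.rng(AC)) for s in col] for col in s_masks]
    _send_ciphertext_columns(ctx, EMC, HELPER, "masks_enc", enc_z)
    _send_ciphertext_columns(ctx, AC, HELPER, "masks_enc", enc_s)
    masks_for_a = _recv_ciphertext_columns(ctx, EMC, HELPER, pk_a.key_id)
    masks_for_b = _recv_ciphertext_columns(ctx, AC, HELPER, pk_b.key_id)

    # 8. helper blinds and routes each party its own (masked) column values.
    to_ac, to_emc = blind_and_route(
        match, helper_a, helper_b, masks_for_a, masks_for_b, pk_a, pk_b
    )
    _send_ciphertext_columns(ctx, HELPER, AC, "blinded_enc", to_ac)
    _send_ciphertext_columns(ctx, HELPER, EMC, "blinded_enc", to_emc)
    got_ac = _recv_ciphertext_columns(ctx, HELPER, AC, pk_a.key_id)
    got_emc = _recv_ciphertext_columns(ctx, HELPER, EMC, pk_b.key_id)

    # 9. decrypt and assemble the final share tables (Table-8 layout).
    dec_ac = [[paillier.decrypt(kp_a.secret_key, c) % p for c in col] for col in got_ac]
    dec_emc = [[paillier.decrypt(kp_b.secret_key, c) % p for c in col] for col in got_emc]
    rows_ac = [
        [dec_ac[c][t] for c in range(m_a)] + [s_masks[c][t] for c in range(m_b)]
        for t in range(k_at_ac)
    ]
    rows_emc = [
        [z_masks[c][t] for c in range(m_a)] + [dec_emc[c][t] for c in range(m_b)]
        for t in range(k_at_emc)
    ]
    table_ac = AdditiveShareTable(AC, joined_names, rows_ac, fp, target)
    table_emc = AdditiveShareTable(EMC, joined_names, rows_emc, fp, target)
    return table_ac, table_emc, match.k
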