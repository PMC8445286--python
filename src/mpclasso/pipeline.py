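"""End-to-end orchestration: secure join -> share casting -> secure training.

One call runs the whole privacy-preserving workflow on two plaintext party
datasets and returns the trained model, its goodness of fit, the intersection
size, and the audit artefacts (transcript + reveal ledger).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import paillier
from .datasets import PlainDataset
from .fields import FieldParams
from .innerjoin import secure_inner_join
from .lasso import EvalReport, GDConfig, LassoModel
from .runtime import ProtocolContext, RevealLedger, Transcript
from .secure import secure_r_squared, train_secure
from .shamir import ShamirEngine, SharedArray


class EmptyIntersectionError(RuntimeError):
    """The datasets share no identifiers; there is nothing to train on."""


@dataclass
class PipelineResult:
    model: LassoModel
    report: EvalReport
    k: int
    transcript: Transcript
    ledger: RevealLedger


def split_target(
    engine: ShamirEngine, shared: SharedArray, column_names: list[str], target: str
) -> tuple[SharedArray, SharedArray]:
    """Split a shared joined table into design matrix and target vector."""
    if target not in column_names:
        raise ValueError(f"target column {target!r} not in joined table")
    ti = column_names.index(target)
    n, m = shared.shape
    xs_shares, ys_shares = {}, {}
    for q, src in shared.shares.items():
        xs, ys = [], []
        for r in range(n):
            row = src[r * m : (r + 1) * m]
            ys.append(row[ti])
            xs.extend(row[:ti] + row[ti + 1 :])
        xs_shares[q], ys_shares[q] = xs, ys
    fld = engine.field
    return (
        SharedArray(xs_shares, (n, m - 1), shared.frac, fld),
        SharedArray(ys_shares, (n,), shared.frac, fld),
    )


def run_pipeline(
    ds_a: PlainDataset,
    ds_b: PlainDataset,
    cfg: GDConfig,
    field: FieldParams | None = None,
    ctx: ProtocolContext | None = None,
    he_bits: int = paillier.DEFAULT_KEY_BITS,
) -> PipelineResult:
    """Secure inner join, cast to (1,3) shares, train Lasso, evaluate R^2.

    The model's objective is filled in from the revealed residual sum of the
    goodness-of-fit step (no extra leakage).  Raises
    :class:`EmptyIntersectionError` when the identifier intersection is empty.
    """
    field = field or FieldParams()
    own_ctx = ctx is None
    ctx = ctx or ProtocolContext()
    try:
        table_ac, table_emc, k = secure_inner_join(ds_a, ds_b, field, ctx, he_bits=he_bits)
        if k == 0:
            raise EmptyIntersectionError("empty intersection: no overlapping identifiers")
        target = table_ac.target_column
        if target is None:
            raise ValueError("no target column designated in either dataset")
        engine = ShamirEngine(ctx, field)
        shared = engine.cast_2of2_to_shamir(table_ac, table_emc)
        Xs, ys = split_target(engine, shared, table_ac.column_names, target)
        model = train_secure(Xs, ys, cfg, engine)
        r2, sums = secure_r_squared(Xs, ys, model, engine)
        n = ys.shape[0]
        model.objective = sums["r2_num"] / n + cfg.lam * float(
            np.abs(model.weights).sum()
        )
        report = EvalReport(
            r_squared=r2,
            mse=sums["r2_num"] / n,
            mae=float("nan"),  # secure MAE not implemented; see docs
            y_mean=float("nan"),
        )
    finally:
        if own_ctx:
            ctx.close()
    return PipelineResult(model, report, k, ctx.bus.transcript, ctx.ledger)
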