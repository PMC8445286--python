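"""Synthetic vertically-partitioned datasets with controlled overlap.

Two organisations -- an insurer holding, e.g., hospitalization data and a
hospital holding lifestyle data -- each own some feature columns for a
partially overlapping set of individuals.  This module generates such data
with a known linear signal so that every downstream protocol stage (secure
join, share casting, secure training) can be validated against an exact
plaintext ground truth, and it packages the small worked join example used
throughout the docs and tests.

Identifiers are opaque zero-padded 7-digit strings.  Feature values are
min-max scaled to [0, 1] by default, matching the pre-processing the secure
pipeline assumes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class PlainDataset:
    """One party's plaintext table: an id column plus numeric feature columns."""

    identifiers: list[str]
    features: np.ndarray  # shape (n_records, n_columns)
    column_names: list[str]
    target_column: str | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if len(set(self.identifiers)) != len(self.identifiers):
            raise ValueError("identifiers must be unique within a dataset")
        if self.features.shape[0] != len(self.identifiers):
            raise ValueError("feature rows must align with identifiers")
        if self.features.shape[1] != len(self.column_names):
            raise ValueError("feature columns must align with column_names")
        if self.target_column is not None and self.target_column not in self.column_names:
            raise ValueError(f"target column {self.target_column!r} not present")

    @property
    def n(self) -> int:
        return len(self.identifiers)

    def column(self, name: str) -> np.ndarray:
        return self.features[:, self.column_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.column_names)
        df.insert(0, "id", self.identifiers)
        return df

    @staticmethod
    def from_frame(df: pd.DataFrame, target_column: str | None = None) -> "PlainDataset":
        if df.columns[0] != "id":
            raise ValueError("first column must be 'id'")
        cols = [c for c in df.columns if c != "id"]
        return PlainDataset(
            identifiers=[str(v) for v in df["id"]],
            features=df[cols].to_numpy(dtype=float),
            column_names=cols,
            target_column=target_column,
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @staticmethod
    def read_csv(path: str | Path, target_column: str | None = None) -> "PlainDataset":
        df = pd.read_csv(path, dtype={"id": str})
        return PlainDataset.from_frame(df, target_column=target_column)


@dataclass
class SyntheticGroundTruth:
    """What the generator knows and the protocols must reproduce."""

    true_weights: np.ndarray | None
    noise_sd: float
    intersection_ids: set[str] = field(default_factory=set)
    joined_table: PlainDataset | None = None
    seed: int | None = None

    def to_json(self) -> dict:
        return {
            "true_weights": None
            if self.true_weights is None
            else [float(w) for w in self.true_weights],
            "noise_sd": self.noise_sd,
            "intersection_ids": sorted(self.intersection_ids),
            "seed": self.seed,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))


def _unique_ids(rng: np.random.Generator, count: int, exclude: set[str] = frozenset()) -> list[str]:
    ids: list[str] = []
    seen = set(exclude)
    while len(ids) < count:
        cand = f"{rng.integers(0, 10**7):07d}"
        if cand not in seen:
            seen.add(cand)
            ids.append(cand)
    return ids


def generate_regression(
    n: int,
    m_total: int,
    noise_sd: float,
    sparsity: float,
    seed: int,
    scale: bool = True,
) -> tuple[PlainDataset, SyntheticGroundTruth]:
    """Sample a dataset with a roughly linear target dependency.

    ``m_total`` predictor columns are drawn uniformly on [0, 1); the target is
    ``X @ w_true + Normal(0, noise_sd)`` with exactly
    ``round(sparsity * m_total)`` entries of ``w_true`` equal to zero.  With
    ``scale=True`` every column (target included) is then min-max scaled to
    [0, 1], the range the secure pipeline assumes.
    """
    if n < 1 or m_total < 1:
        raise ValueError("n and m_total must be positive")
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    X = rng.random((n, m_total))
    w = rng.normal(0.0, 1.0, m_total)
    n_zero = round(sparsity * m_total)
    if n_zero:
        zero_idx = rng.choice(m_total, size=n_zero, replace=False)
        w[zero_idx] = 0.0
    y = X @ w + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)

    table = np.column_stack([X, y])
    if scale:
        lo = table.min(axis=0)
        span = table.max(axis=0) - lo
        span[span == 0] = 1.0
        table = (table - lo) / span

    names = [f"f{i + 1:02d}" for i in range(m_total)] + ["target"]
    ids = _unique_ids(rng, n)
    ds = PlainDataset(ids, table, names, target_column="target")
    gt = SyntheticGroundTruth(
        true_weights=w,
        noise_sd=noise_sd,
        intersection_ids=set(ids),
        joined_table=ds,
        seed=seed,
    )
    return ds, gt


def vertical_split(
    full: PlainDataset,
    m_A: int,
    overlap_fraction: float,
    seed: int,
    ground_truth: SyntheticGroundTruth | None = None,
) -> tuple[PlainDataset, PlainDataset, SyntheticGroundTruth]:
    """Split a dataset column-wise between two parties with partial id overlap.

    Party A receives the first ``m_A`` feature columns, party B the remaining
    columns including the target.  Both parties keep the same
    ``floor(overlap_fraction * n)`` genuine records and each additionally
    receives ``ceil((1 - overlap_fraction) * n)`` filler records whose
    identifiers do not occur at the other party.  Filler feature values are
    bootstrap-resampled from the party's own genuine columns so that overlap
    membership cannot be read off the marginal distributions.
    """
    n_feat = len(full.column_names) - (1 if full.target_column else 0)
    if not 1 <= m_A < n_feat:
        raise ValueError(f"m_A must be in [1, {n_feat - 1}]")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = full.n
    n_fill = math.ceil((1.0 - overlap_fraction) * n)
    n_keep = n - n_fill
    keep_idx = np.sort(rng.choice(n, size=n_keep, replace=False))
    keep_ids = [full.identifiers[i] for i in keep_idx]

    feat_names = [c for c in full.column_names if c != full.target_column]
    cols_a = feat_names[:m_A]
    cols_b = feat_names[m_A:] + ([full.target_column] if full.target_column else [])

    def build_party(cols: list[str], target: str | None) -> PlainDataset:
        col_idx = [full.column_names.index(c) for c in cols]
        genuine = full.features[np.ix_(keep_idx, col_idx)]
        filler = np.empty((n_fill, len(cols)))
        for j, ci in enumerate(col_idx):
            filler[:, j] = rng.choice(full.features[:, ci], size=n_fill, replace=True)
        fill_ids = _unique_ids(rng, n_fill, exclude=set(full.identifiers))
        rows = np.vstack([genuine, filler])
        ids = keep_ids + fill_ids
        order = rng.permutation(len(ids))
        return PlainDataset(
            [ids[i] for i in order], rows[order], cols, target_column=target
        )

    ds_a = build_party(cols_a, None)
    ds_b = build_party(cols_b, full.target_column)

    joined = PlainDataset(
        keep_ids,
        full.features[np.ix_(keep_idx, [full.column_names.index(c) for c in cols_a + cols_b])],
        cols_a + cols_b,
        target_column=full.target_column,
    )
    gt = SyntheticGroundTruth(
        true_weights=None if ground_truth is None else ground_truth.true_weights,
        noise_sd=0.0 if ground_truth is None else ground_truth.noise_sd,
        intersection_ids=set(keep_ids),
        joined_table=joined,
        seed=seed,
    )
    return ds_a, ds_b, gt


def plaintext_inner_join(ds_a: PlainDataset, ds_b: PlainDataset) -> PlainDataset:
    """Ordinary hash-join on identifiers; the oracle the secure join must match."""
    df = ds_a.to_frame().merge(ds_b.to_frame(), on="id", how="inner", validate="1:1")
    target = ds_b.target_column or ds_a.target_column
    return PlainDataset.from_frame(df, target_column=target)


def toy_tables() -> tuple[PlainDataset, PlainDataset, set[str]]:
    """The small insurer/hospital worked example used in the docs.

    The insurer holds hospitalization days, the hospital holds weekly exercise
    hours; exactly three identifiers occur in both tables.  Only the first
    joined record's values (0 hospitalization days, 0 exercise hours) are part
    of the published example; the remaining cells are synthetic filler.
    """
    ds_a = PlainDataset(
        identifiers=["0000001", "1111115", "5555558", "7777779"],
        features=np.array([[0.0], [1.0], [7.0], [9.0]]),
        column_names=["hospitalization_days"],
    )
    ds_b = PlainDataset(
        identifiers=["0000001", "1111112", "1111115", "7777779", "9999993"],
        features=np.array([[0.0], [5.0], [2.0], [1.0], [3.0]]),
        column_names=["exercise_hours_per_week"],
    )
    return ds_a, ds_b, {"0000001", "1111115", "7777779"}
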