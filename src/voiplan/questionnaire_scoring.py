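"""Score STAIT and STICSAT item responses into four trait-anxiety factors.

Items are coded 1-4 (1 = no anxiety), with the STAIT anxiety-absent items
reverse coded; Bartlett weighted-least-squares scores are computed against a
supplied oblique factor-loading configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import FACTOR_NAMES

__all__ = [
    "STAIT_REVERSE_ITEMS",
    "STAIT_N_ITEMS",
    "STICSAT_N_ITEMS",
    "N_ITEMS_TOTAL",
    "STAIT_LABELS",
    "STICSAT_LABELS",
    "LoadingConfig",
    "code_items",
    "bartlett_scores",
    "factor_correlations",
]

STAIT_N_ITEMS = 20
STICSAT_N_ITEMS = 21
N_ITEMS_TOTAL = STAIT_N_ITEMS + STICSAT_N_ITEMS

#: STAIT anxiety-absent item numbers (1-based); responses are reverse coded.
STAIT_REVERSE_ITEMS: tuple[int, ...] = (1, 3, 6, 7, 10, 13, 14, 16, 19)

#: Response labels in ascending order of endorsement for each inventory.
STAIT_LABELS: tuple[str, ...] = ("almost never", "sometimes", "often", "almost always")
STICSAT_LABELS: tuple[str, ...] = ("not at all", "a little", "moderately", "very much so")


class ItemCodingError(ValueError):
    """Raised when responses are missing or outside the labelled categories."""


@dataclass(frozen=True)
class LoadingConfig:
    """41 x 4 factor loading matrix with item uniquenesses.

    Rows are ordered STAIT 1-20 then STICSAT 1-21; columns follow
    ``FACTOR_NAMES``.  Uniquenesses must be strictly positive.
    """

    loadings: np.ndarray
    uniquenesses: np.ndarray
    factor_names: tuple[str, ...] = field(default=FACTOR_NAMES)

    def __post_init__(self) -> None:
        lam = np.asarray(self.loadings, dtype=float)
        psi = np.asarray(self.uniquenesses, dtype=float)
        if lam.shape != (N_ITEMS_TOTAL, len(self.factor_names)):
            raise ValueError(
                f"loadings must be {N_ITEMS_TOTAL}x{len(self.factor_names)}, got {lam.shape}"
            )
        if psi.shape != (N_ITEMS_TOTAL,):
            raise ValueError(f"uniquenesses must have length {N_ITEMS_TOTAL}")
        if np.any(psi <= 0):
            raise ValueError("uniquenesses must be strictly positive")
        if np.linalg.matrix_rank(lam) < lam.shape[1]:
            raise np.linalg.LinAlgError("loading matrix is rank deficient")
        object.__setattr__(self, "loadings", lam)
        object.__setattr__(self, "uniquenesses", psi)

    @classmethod
    def from_file(cls, path: str | Path) -> "LoadingConfig":
        """Load a YAML/JSON config with keys loadings, uniquenesses, factor_names."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            loadings=np.asarray(raw["loadings"], dtype=float),
            uniquenesses=np.asarray(raw["uniquenesses"], dtype=float),
            factor_names=tuple(raw.get("factor_names", FACTOR_NAMES)),
        )

    def to_file(self, path: str | Path) -> None:
        payload = {
            "loadings": self.loadings.tolist(),
            "uniquenesses": self.uniquenesses.tolist(),
            "factor_names": list(self.factor_names),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def synthetic_default(cls, seed: int = 1234) -> "LoadingConfig":
        """Shipped simple-structure stand-in for the external loading file."""
        from .synthetic_data import default_loadings

        lam, psi = default_loadings(seed)
        return cls(loadings=lam, uniquenesses=psi)


def _label_maps() -> dict[str, dict[str, int]]:
    return {
        "STAIT": {lab: i + 1 for i, lab in enumerate(STAIT_LABELS)},
        "STICSAT": {lab: i + 1 for i, lab in enumerate(STICSAT_LABELS)},
    }


def code_items(responses: pd.DataFrame) -> pd.DataFrame:
    """Code raw labelled responses into the 41-column item matrix.

    ``responses`` is long format with columns subject_id, inventory
    ({STAIT, STICSAT}), item_index (1-based within inventory), and
    response (label string or already-numeric 1..4 endorsement level).
    Anxiety-present items map ascending; STAIT anxiety-absent items are
    reverse coded (5 - x).  Output is wide: one row per subject, columns
    item_01..item_41 (STAIT 1-20 then STICSAT 1-21), values 1..4 where 1
    means no anxiety.
    """
    required = {"subject_id", "inventory", "item_index", "response"}
    missing_cols = required - set(responses.columns)
    if missing_cols:
        raise ItemCodingError(f"missing columns: {sorted(missing_cols)}")
    maps = _label_maps()
    df = responses.copy()

    def to_level(row) -> int:
        r = row["response"]
        inv = row["inventory"]
        if inv not in maps:
            raise ItemCodingError(f"unknown inventory {inv!r}")
        if isinstance(r, str):
            label = r.strip().lower()
            if label not in maps[inv]:
                raise ItemCodingError(f"unknown response label {r!r} for {inv}")
            return maps[inv][label]
        level = int(r)
        if not 1 <= level <= 4 or level != r:
            raise ItemCodingError(f"response must be in 1..4, got {r!r}")
        return level

    df["level"] = df.apply(to_level, axis=1)
    reverse = df["inventory"].eq("STAIT") & df["item_index"].isin(STAIT_REVERSE_ITEMS)
    df["coded"] = np.where(reverse, 5 - df["level"], df["level"])
    df["column"] = np.where(
        df["inventory"].eq("STAIT"),
        df["item_index"],
        df["item_index"] + STAIT_N_ITEMS,
    )
    bad_idx = (
        (df["inventory"].eq("STAIT") & ~df["item_index"].between(1, STAIT_N_ITEMS))
        | (df["inventory"].eq("STICSAT") & ~df["item_index"].between(1, STICSAT_N_ITEMS))
    )
    if bad_idx.any():
        raise ItemCodingError(
            f"item_index out of range in rows {df.index[bad_idx].tolist()}"
        )
    wide = df.pivot_table(
        index="subject_id", columns="column", values="coded", aggfunc="first"
    )
    expected = list(range(1, N_ITEMS_TOTAL + 1))
    incomplete = wide[wide[wide.columns.intersection(expected)].isna().any(axis=1)]
    missing_any = set(expected) - set(wide.columns)
    if missing_any or len(incomplete):
        offenders = {}
        for sid, row in wide.iterrows():
            absent = [c for c in expected if c not in wide.columns or pd.isna(row.get(c))]
            if absent:
                offenders[sid] = absent
        raise ItemCodingError(f"incomplete responses; missing items per subject: {offenders}")
    wide = wide[expected].astype(np.int64)
    wide.columns = [f"item_{c:02d}" for c in expected]
    return wide.reset_index()


def bartlett_scores(
    coded_items: pd.DataFrame, cfg: LoadingConfig
) -> pd.DataFrame:
    """Bartlett weighted-least-squares factor scores.

    Items are standardized column-wise against the analysis sample, then
    scores = (L' Psi^-1 L)^-1 L' Psi^-1 z per subject.
    """
    item_cols = [c for c in coded_items.columns if c.startswith("item_")]
    if len(item_cols) != N_ITEMS_TOTAL:
        raise ValueError(f"expected {N_ITEMS_TOTAL} item columns, got {len(item_cols)}")
    x = coded_items[item_cols].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        # zero-variance items carry no information; keep them centred at 0
        sd = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=0)) / sd
    lam = cfg.loadings
    w = lam.T / cfg.uniquenesses  # L' Psi^-1, shape (4, 41)
    m = w @ lam
    scores = np.linalg.solve(m, w @ z.T).T
    out = pd.DataFrame(scores, columns=list(cfg.factor_names))
    id_col = "subject_id" if "subject_id" in coded_items.columns else "subject"
    if id_col in coded_items.columns:
        out.insert(0, "subject", coded_items[id_col].to_numpy())
    return out


def bartlett_scores_from_z(z: np.ndarray, cfg: LoadingConfig) -> np.ndarray:
    """Bartlett projection of already-standardized item rows (no re-centering)."""
    lam = cfg.loadings
    w = lam.T / cfg.uniquenesses
    return np.linalg.solve(w @ lam, w @ np.atleast_2d(z).T).T


def factor_correlations(scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the four factor scores."""
    cols = [c for c in scores.columns if c in FACTOR_NAMES]
    if len(scores) < 3:
        raise ValueError("need at least 3 subjects to correlate factors")
    x = scores[cols].to_numpy(dtype=float)
    if np.any(x.std(axis=0, ddof=0) == 0):
        zero = [c for c, s in zip(cols, x.std(axis=0, ddof=0)) if s == 0]
        raise ValueError(f"zero-variance factors: {zero}")
    corr = np.corrcoef(x, rowvar=False)
    return pd.DataFrame(corr, index=cols, columns=cols)
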