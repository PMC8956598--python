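"""Analysis-ready profile tables: well aggregation, batch/plate-layout
centering, per-column L2 scaling, and persistence.

All tables are pandas DataFrames carrying the metadata key columns
(batch, plate, layout, well, line_id, donor_id, biopsy_index, disease_state,
mutation_group) plus value columns (embedding dimensions ``e000..e319`` or
engineered feature names).  The implemented normalization order follows the
profiling convention: center at the cell/tile level per (batch, layout), then
take the unweighted well mean; engineered features and image statistics are
additionally scaled to unit L2 norm per column across all examples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

META_COLS = ["batch", "plate", "layout", "well", "line_id", "donor_id",
             "biopsy_index", "disease_state", "mutation_group", "age", "sex",
             "pair_id"]


def value_columns(table: pd.DataFrame) -> list[str]:
    drop = set(META_COLS) | {"tile", "object", "path", "QC_DegenerateObject"}
    return [c for c in table.columns
            if c not in drop and pd.api.types.is_numeric_dtype(table[c])]


class IntegrityError(ValueError):
    pass


def well_aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """One row per (batch, plate, well): the arithmetic mean of every value
    column over the well's cells/tiles; metadata carried through.

    Conflicting metadata within a well raises :class:`IntegrityError`.
    """
    vcols = value_columns(table)
    meta = [c for c in META_COLS if c in table.columns and c not in ("batch", "plate")]
    keys = ["batch", "plate", "well"]
    for key, grp in table.groupby(keys):
        check = [c for c in meta if c != "well"]
        if (grp[check].nunique() > 1).any():
            bad = [c for c in check if grp[c].nunique() > 1]
            raise IntegrityError(f"conflicting metadata {bad} within well {key}")
    agg = {c: "mean" for c in vcols}
    agg.update({c: "first" for c in meta if c != "well"})
    out = table.groupby(keys, as_index=False).agg(agg)
    return out[[c for c in META_COLS if c in out.columns] + vcols]


@dataclass
class NormalizationState:
    """Per-(batch, layout) mean vectors and per-column L2 norms, reapplicable."""

    columns: list
    group_means: dict = field(default_factory=dict)  # (batch, layout) -> np.ndarray
    l2_norms: np.ndarray | None = None
    zero_norm_columns: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "columns": list(self.columns),
            "group_means": {f"{b}|{l}": m.tolist()
                            for (b, l), m in self.group_means.items()},
            "l2_norms": None if self.l2_norms is None else self.l2_norms.tolist(),
            "zero_norm_columns": list(self.zero_norm_columns),
        })

    @classmethod
    def from_json(cls, s: str) -> "NormalizationState":
        d = json.loads(s)
        gm = {}
        for k, v in d["group_means"].items():
            b, l = k.split("|")
            gm[(int(b), int(l))] = np.asarray(v)
        return cls(columns=d["columns"], group_means=gm,
                   l2_norms=None if d["l2_norms"] is None else np.asarray(d["l2_norms"]),
                   zero_norm_columns=d["zero_norm_columns"])


def center_by_batch_layout(
    table: pd.DataFrame, state: NormalizationState | None = None
) -> tuple[pd.DataFrame, NormalizationState]:
    """Subtract the per-(batch, layout) mean from every value column.

    With ``state`` given, reapplies the stored means (unseen groups raise);
    otherwise computes and records them.
    """
    for col in ("batch", "layout"):
        if col not in table.columns:
            raise ValueError(f"table lacks the {col!r} column")
    vcols = value_columns(table)
    out = table.copy()
    if state is None:
        state = NormalizationState(columns=vcols)
        for (b, l), grp in table.groupby(["batch", "layout"]):
            if len(grp) == 0:
                continue
            state.group_means[(int(b), int(l))] = grp[vcols].mean().to_numpy()
    for (b, l), grp in table.groupby(["batch", "layout"]):
        key = (int(b), int(l))
        if key not in state.group_means:
            raise ValueError(f"no stored mean for group batch={b}, layout={l}")
        out.loc[grp.index, vcols] = (
            grp[vcols].to_numpy() - state.group_means[key][None, :]
        )
    return out, state


def l2_scale_columns(
    table: pd.DataFrame, state: NormalizationState | None = None
) -> tuple[pd.DataFrame, NormalizationState]:
    """Divide each value column by its L2 norm across rows; zero-norm columns
    are left unchanged and flagged in the state."""
    vcols = value_columns(table)
    out = table.copy()
    if state is None:
        state = NormalizationState(columns=vcols)
    if state.l2_norms is None:
        vals = table[vcols].to_numpy(dtype=float)
        norms = np.linalg.norm(vals, axis=0)
        state.l2_norms = norms
        state.zero_norm_columns = [c for c, n in zip(vcols, norms) if n == 0]
    norms = np.where(state.l2_norms == 0, 1.0, state.l2_norms)
    out[vcols] = out[vcols].to_numpy(dtype=float) / norms[None, :]
    return out, state


def assemble_dataset(manifest: pd.DataFrame, values: pd.DataFrame,
                     on=("batch", "plate", "well", "tile")) -> tuple[pd.DataFrame, dict]:
    """Inner-join stage outputs onto the manifest provenance keys.

    Returns the joined table and an exceptions report listing manifest keys
    with no values and value keys with no manifest row (never silently
    dropped)."""
    on = [c for c in on if c in values.columns and c in manifest.columns]
    meta_cols = [c for c in manifest.columns if c not in values.columns or c in on]
    joined = manifest[meta_cols].merge(values, on=on, how="inner")
    mkeys = set(map(tuple, manifest[on].itertuples(index=False)))
    vkeys = set(map(tuple, values[on].itertuples(index=False)))
    report = {
        "n_joined": len(joined),
        "missing_values": sorted(mkeys - vkeys),
        "orphan_values": sorted(vkeys - mkeys),
    }
    return joined, report


def save_table(table: pd.DataFrame, path: str) -> None:
    """Persist a profile table (parquet for .parquet, else CSV)."""
    if path.endswith(".parquet"):
        table.to_parquet(path, index=False)
    else:
        table.to_csv(path, index=False)


def load_table(path: str) -> pd.DataFrame:
    if path.endswith(".parquet"):
        return pd.read_parquet(path)
    return pd.read_csv(path)
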