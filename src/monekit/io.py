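"""Reading and writing the on-disk table formats.

Two physical formats share one logical schema: tab-delimited text (portable,
>= 15 significant digits) and Parquet (columnar binary, bit-exact round
trip).  Format is chosen by file extension: ``.parquet`` is binary,
anything else is TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .data import ExpressionMatrix, MoneMatrix, SlideMeta, meta_frame

__all__ = [
    "write_table",
    "read_table",
    "write_mones",
    "read_mones",
    "write_expression",
    "read_expression",
    "write_meta",
    "read_meta",
]

_FLOAT_FMT = "%.17g"


def _is_parquet(path: str | Path) -> bool:
    return str(path).endswith(".parquet")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    if _is_parquet(path):
        df.to_parquet(path, index=index)
    else:
        df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    if _is_parquet(path):
        df = pd.read_parquet(path)
        if index_col is not None and index_col in df.columns:
            df = df.set_index(index_col)
        return df
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_meta(meta: Sequence[SlideMeta], path: str | Path) -> None:
    write_table(meta_frame(meta), path)


def read_meta(path: str | Path) -> list[SlideMeta]:
    df = read_table(path)
    return [
        SlideMeta(
            slide_id=str(r.slide_id),
            patient_id=str(r.patient_id),
            cancer_type=str(r.cancer_type),
            lesion=str(r.lesion),
            preparation=str(r.preparation),
            vial_id=str(r.vial_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_mones(mones: MoneMatrix, path: str | Path) -> None:
    """Write a slide x feature matrix; row keys in column 1 (``slide_id``)."""
    df = mones.to_frame().reset_index()
    write_table(df, path)


def read_mones(path: str | Path, meta: Sequence[SlideMeta]) -> MoneMatrix:
    df = read_table(path, index_col="slide_id")
    order = [m.slide_id for m in meta]
    df = df.loc[order]
    feature_ids = [int(str(c).removeprefix("mone_")) for c in df.columns]
    return MoneMatrix(df.to_numpy(), meta, feature_ids)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    write_table(expr.to_frame().reset_index(), path)


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = read_table(path, index_col="vial_id")
    return ExpressionMatrix(df.to_numpy(), list(df.index), list(df.columns))
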