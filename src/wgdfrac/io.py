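"""Readers and writers for the tab-separated dialects of the pipeline.

The empirical input is a SynMap-like gene-pair table: one row per
syntenically validated homolog pair with two gene identifiers and a
similarity score.  Scores above 1 are interpreted as percentages and
divided by 100 on ingest, so both '0.875' and '87.5' mean the same thing.

Every writer embeds the effective configuration and seed as commented
header lines, so a deterministic run can be reproduced byte-for-byte from
its own output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .schedule import ValidationError
from .similarity import MixtureModel

__all__ = [
    "PairTable",
    "read_pair_table",
    "write_pair_table",
    "write_tsv_with_header",
    "read_component_table",
    "read_commented_tsv",
]

log = logging.getLogger("wgdfrac")


@dataclass(frozen=True)
class PairTable:
    """A validated gene-pair similarity table.

    ``data`` has columns gene_id_1, gene_id_2, similarity (in [0, 1]) and
    optionally origin_event (generator ground truth, ignored by
    inference).  Counters record what ingest had to clean up.
    """

    data: pd.DataFrame
    n_malformed: int = 0
    n_duplicates: int = 0
    percent_converted: int = 0

    @property
    def similarities(self) -> np.ndarray:
        return self.data["similarity"].to_numpy()

    def __len__(self) -> int:
        return len(self.data)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except (TypeError, ValueError):
        return False


def read_pair_table(
    path: Union[str, Path],
    *,
    max_malformed_frac: float = 0.10,
    deduplicate: bool = True,
) -> PairTable:
    """Read a 3(+1)-column TSV of gene pairs and similarity scores.

    A header row is auto-detected (non-numeric third field).  Rows with a
    missing or unparseable similarity, or one outside [0, 100], count as
    malformed; more than ``max_malformed_frac`` of them is a hard error.
    Duplicate unordered pairs are dropped with a warning.  Values above 1
    are treated as percentages.
    """
    path = Path(path)
    rows: List[Tuple[str, str, float, Optional[int]]] = []
    n_malformed = 0
    n_percent = 0
    n_total = 0
    first_content = True
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if first_content:
                first_content = False
                if len(fields) >= 3 and not _is_number(fields[2]):
                    continue  # header row
            n_total += 1
            if len(fields) < 3 or not _is_number(fields[2]):
                n_malformed += 1
                continue
            sim = float(fields[2])
            if sim > 1.0:
                if sim > 100.0 or not math.isfinite(sim):
                    n_malformed += 1
                    continue
                sim /= 100.0
                n_percent += 1
            if not (0.0 <= sim <= 1.0) or not math.isfinite(sim):
                n_malformed += 1
                continue
            origin = None
            if len(fields) >= 4 and _is_number(fields[3]):
                origin = int(float(fields[3]))
            rows.append((fields[0], fields[1], sim, origin))

    if n_total == 0:
        raise ValidationError(f"{path}: empty pair table")
    if n_malformed > max_malformed_frac * n_total:
        raise ValidationError(
            f"{path}: {n_malformed}/{n_total} malformed rows exceeds "
            f"{max_malformed_frac:.0%} tolerance"
        )
    if n_malformed:
        log.warning("%s: skipped %d malformed rows", path, n_malformed)

    df = pd.DataFrame(rows, columns=["gene_id_1", "gene_id_2", "similarity", "origin_event"])
    if df["origin_event"].isna().all():
        df = df.drop(columns=["origin_event"])

    n_dup = 0
    if deduplicate and len(df):
        key = df[["gene_id_1", "gene_id_2"]].apply(lambda r: tuple(sorted(r)), axis=1)
        keep = ~key.duplicated()
        n_dup = int((~keep).sum())
        if n_dup:
            log.warning("%s: dropped %d duplicate unordered pairs", path, n_dup)
            df = df[keep].reset_index(drop=True)
    return PairTable(df, n_malformed, n_dup, n_percent)


def _header_lines(header: Optional[Dict[str, object]]) -> str:
    if not header:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in header.items())


def write_tsv_with_header(
    df: pd.DataFrame, path: Union[str, Path], header: Optional[Dict[str, object]] = None
) -> None:
    """Write a TSV preceded by '# key: value' comment lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(header))
        df.to_csv(fh, sep="\t", index=False)


def write_pair_table(
    table: Union[PairTable, pd.DataFrame],
    path: Union[str, Path],
    header: Optional[Dict[str, object]] = None,
    *,
    include_origin: bool = True,
) -> None:
    df = table.data if isinstance(table, PairTable) else table
    if not include_origin and "origin_event" in df.columns:
        df = df.drop(columns=["origin_event"])
    write_tsv_with_header(df, path, header)


def read_commented_tsv(path: Union[str, Path]) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Read a TSV written by :func:`write_tsv_with_header`, returning the
    table and the parsed '# key: value' header."""
    header: Dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if ":" in stripped:
                k, v = stripped.split(":", 1)
                header[k.strip()] = v.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    return df, header


def read_component_table(path: Union[str, Path]) -> Tuple[MixtureModel, Dict[str, str]]:
    """Read a fitted component table (mean, sd, weight, count) back into a
    :class:`MixtureModel`."""
    df, header = read_commented_tsv(path)
    for col in ("mean", "sd", "weight"):
        if col not in df.columns:
            raise ValidationError(f"{path}: component table lacks column {col!r}")
    counts = None
    if "count" in df.columns and not df["count"].isna().any():
        counts = tuple(int(c) for c in df["count"])
    mixture = MixtureModel(
        tuple(float(x) for x in df["mean"]),
        tuple(float(x) for x in df["sd"]),
        tuple(float(x) for x in df["weight"]),
        counts,
    )
    return mixture, header
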