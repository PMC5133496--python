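"""Readers, writers and the run manifest.

All tables are TSV with '.' decimal separators and 'NA' for missing
values; gene sets can be exported as GMT lines.  ``write_results`` writes
every artifact plus a manifest JSON carrying file checksums, the run
configuration and the seed, so identical runs produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "IOError_",
    "read_expression",
    "write_expression",
    "read_phenotypes",
    "write_phenotypes",
    "write_gmt",
    "read_gmt",
    "write_results",
]

logger = logging.getLogger(__name__)

NA_REP = "NA"


class IOError_(ValueError):
    """Malformed input file."""


def read_expression(path: str | Path) -> pd.DataFrame:
    """Probes-by-samples TSV: first column probe id, header of sample ids.

    Gzip input is accepted (by file suffix).  Duplicate probe ids or
    non-numeric cells raise.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP])
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise IOError_(f"{path}: duplicate probe ids: {list(dups[:5])}")
    bad = [c for c in df.columns
           if not pd.api.types.is_numeric_dtype(df[c])]
    if bad:
        raise IOError_(f"{path}: non-numeric cells in column(s) {bad[:5]}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="probe_id", na_rep=NA_REP)


def read_phenotypes(path: str | Path,
                    required: tuple[str, ...] = ("sample_id",)) -> pd.DataFrame:
    """Phenotype/covariate TSV indexed by sample_id; extra columns kept."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_REP])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing required column(s): {missing}")
    df["sample_id"] = df["sample_id"].astype(str)
    if df["sample_id"].duplicated().any():
        raise IOError_(f"{path}: duplicate sample ids")
    return df.set_index("sample_id")


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, sep="\t", index_label="sample_id", na_rep=NA_REP)


def write_gmt(gene_sets: Mapping[str, tuple[str, list[str]]],
              path: str | Path) -> None:
    """GMT lines: set name, description, then member probe ids."""
    with open(path, "w") as fh:
        for name, (description, genes) in gene_sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    out: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise IOError_(f"{path}: malformed GMT line")
            out[parts[0]] = (parts[1], parts[2:])
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(
    outdir: str | Path,
    artifacts: Mapping[str, object],
    config: Mapping | None = None,
    seed: int | None = None,
    errors: Mapping[str, str] | None = None,
) -> dict:
    """Write artifacts and a checksummed manifest.

    ``artifacts`` maps file names to DataFrames (written as TSV; an index
    named 'probe_id'/'sample_id' is kept), strings (written verbatim) or
    dicts (written as sorted-key JSON).  Partial failures can be recorded
    via ``errors``; the manifest is written regardless and returned.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, obj in artifacts.items():
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            index = obj.index.name is not None
            obj.to_csv(path, sep="\t", index=index, na_rep=NA_REP)
        elif isinstance(obj, (dict, list)):
            path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(str(obj))
        files[name] = {"sha256": _sha256(path), "bytes": path.stat().st_size}
    manifest = {
        "files": files,
        "config": dict(config) if config else {},
        "seed": seed,
        "errors": dict(errors) if errors else {},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
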