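"""Reading and writing the pipeline's file formats.

Time series are per-subject TSV/CSV tables, rows = volumes, columns =
regions, with a mandatory header row of node labels.  Phenotypes are a
single CSV with one row per subject.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .stats import check_phenotype
from .windows import ROITimeSeries

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_phenotype",
    "write_phenotype",
    "load_timeseries_dir",
]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_timeseries(path, tr_s: float) -> ROITimeSeries:
    """Read one subject's volumes x regions table (TSV or CSV, header row)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return ROITimeSeries(
        data=df.to_numpy(dtype=float),
        tr_s=tr_s,
        node_labels=tuple(map(str, df.columns)),
    )


def write_timeseries(path, ts: ROITimeSeries) -> None:
    path = Path(path)
    pd.DataFrame(ts.data, columns=list(ts.node_labels)).to_csv(
        path, sep=_sep_for(path), index=False
    )


def read_phenotype(path) -> pd.DataFrame:
    """Read and validate the phenotype CSV."""
    pheno = pd.read_csv(path)
    check_phenotype(pheno)
    return pheno


def write_phenotype(path, pheno: pd.DataFrame) -> None:
    pheno.to_csv(path, index=False)


def load_timeseries_dir(data_dir, tr_s: float, pattern: str = "*.tsv") -> dict[str, ROITimeSeries]:
    """Load every time-series file in a directory; subject id = file stem."""
    data_dir = Path(data_dir)
    files = sorted(data_dir.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no '{pattern}' time-series files in {data_dir}")
    return {f.stem: read_timeseries(f, tr_s) for f in files}
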