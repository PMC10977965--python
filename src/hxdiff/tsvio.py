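"""TSV dialects with a ``#key=value`` metadata header.

Every table written by the pipeline records the conventions that shaped it
(f_D2O, n_term_excluded, bin edges, seeds ...) in comment lines before the
header row, so that no defaulted decision is hidden from the output.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_tsv(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"#{key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


def write_spectrum_tsv(spectrum, path: str | Path) -> Path:
    """Two-column m/z / intensity TSV for one peptide's stick spectrum."""
    df = pd.DataFrame({"mz": spectrum.mz, "intensity": spectrum.intensity})
    return write_tsv(df, path, {"charge": spectrum.charge})


def read_spectrum_tsv(path: str | Path):
    from .uptake import Spectrum

    df, meta = read_tsv(path)
    if "charge" not in meta:
        raise ValueError(f"{path}: spectrum TSV is missing the #charge= header")
    return Spectrum(df["mz"].to_numpy(), df["intensity"].to_numpy(), int(meta["charge"]))


def read_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    metadata: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].rstrip("\n").partition("=")
            metadata[key] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return df, metadata
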