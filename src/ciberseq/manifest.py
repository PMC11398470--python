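"""Sample manifest: which FASTQ belongs to which sample, condition and channel.

Each amplicon library is sequenced separately per reporter channel, so one
biological sample contributes two rows (channel "red" for the
mCherry-linked barcode, "ir" for the iRFP-linked control barcode).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CHANNELS = ("red", "ir")
MANIFEST_COLUMNS = ["fastq_path", "sample_id", "condition", "replicate", "channel"]


def validate_manifest(df: pd.DataFrame, require_paths: bool = False) -> pd.DataFrame:
    """Validate and normalize a manifest DataFrame.

    Ensures the required columns are present, channels are valid, and
    (sample_id, channel) pairs are unique.  With ``require_paths`` the
    referenced FASTQ files must exist.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    df = df[MANIFEST_COLUMNS].copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["condition"] = df["condition"].astype(str)
    df["replicate"] = df["replicate"].astype(str)
    df["channel"] = df["channel"].astype(str)
    bad = set(df["channel"]) - set(CHANNELS)
    if bad:
        raise ValueError(f"unknown channels in manifest: {sorted(bad)}")
    dup = df.duplicated(subset=["sample_id", "channel"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"duplicate (sample_id, channel) in manifest: "
            f"({row.sample_id}, {row.channel})")
    if require_paths:
        for p in df["fastq_path"]:
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
    return df.reset_index(drop=True)


def read_manifest(path: str | Path, require_paths: bool = False) -> pd.DataFrame:
    """Read a TSV/CSV manifest with header (fastq_path, sample_id, condition,
    replicate, channel)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    out = validate_manifest(df, require_paths=require_paths)
    # resolve relative fastq paths against the manifest location
    base = Path(path).parent
    out["fastq_path"] = [str(p) if Path(p).is_absolute() else str(base / p)
                         for p in out["fastq_path"]]
    return out


def check_factorial(df: pd.DataFrame) -> None:
    """Assert that conditions x replicates x channels form a full grid."""
    counts = df.groupby(["condition", "replicate"])["channel"].nunique()
    if counts.nunique() > 1 or (len(counts) and counts.iloc[0] != len(CHANNELS)):
        raise ValueError("manifest is not a full condition x replicate x channel grid")
    per_cond = df.groupby("condition")["replicate"].nunique()
    if per_cond.nunique() > 1:
        raise ValueError("conditions have unequal replicate counts")
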