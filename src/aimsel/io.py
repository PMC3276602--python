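"""Readers and writers for the on-disk formats, plus the shared-SNP filter.

Everything is plain text: TSV for tables, scores, panels, genotypes,
estimates and truth; JSON for reports and provenance.  Two frequency
dialects are read:

* ``tsv`` — columns marker_id, chrom, pos, freq_<pop>... (reference-
  allele frequency per population), optional ref_allele/alt_allele and
  missing_fraction;
* ``hapmap-freq`` — the whitespace-delimited per-population allele-
  frequency files distributed with HapMap phase III (one file per
  population, merged by rs id).

Coordinates are 1-based inclusive bp.  Strand is ignored: only
frequencies are consumed, and every measure is invariant to the choice
of reference allele.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry import AncestryEstimate, GenotypeMatrix
from .measures import FrequencyTable, MeasureScores
from .panels import Panel, SelectionRule
from .simulate import SimTruth

__all__ = [
    "read_frequency_table",
    "write_frequency_table",
    "read_hapmap_frequencies",
    "filter_shared",
    "read_scores",
    "write_scores",
    "read_panel",
    "write_panel",
    "read_genotypes",
    "write_genotypes",
    "read_truth",
    "write_truth",
    "write_estimates",
    "write_json",
    "file_checksum",
]

logger = logging.getLogger("aimsel")


def file_checksum(path) -> str:
    return hashlib.md5(Path(path).read_bytes()).hexdigest()


# ----------------------------------------------------------------------
# frequency tables
# ----------------------------------------------------------------------

def read_frequency_table(path, dialect: str = "tsv") -> FrequencyTable:
    """Read a frequency table; see module docstring for dialects."""
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        for col in ("marker_id", "chrom", "pos"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        freq_cols = [c for c in df.columns if c.startswith("freq_")]
        if not freq_cols:
            raise ValueError(f"{path}: no freq_<pop> columns")
        bad = pd.Series(False, index=df.index)
        for c in freq_cols:
            vals = pd.to_numeric(df[c], errors="coerce")
            bad |= ((vals < 0) | (vals > 1)) & vals.notna()
            df[c] = vals
        bad |= df["pos"].isna()
        if bad.any():
            logger.warning("%s: rejected %d malformed rows", path, int(bad.sum()))
            df = df[~bad]
        df["chrom"] = df["chrom"].astype(str)
        return FrequencyTable(df.reset_index(drop=True))
    if dialect == "hapmap-freq":
        raise ValueError("use read_hapmap_frequencies for per-population files")
    raise ValueError(f"unknown dialect {dialect!r}")


def write_frequency_table(table: FrequencyTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


_HAPMAP_SHORT_COLS = [
    "rs", "chrom", "pos", "strand",
    "ref_allele", "ref_freq", "other_allele", "other_freq",
]


def _read_hapmap_one(path) -> pd.DataFrame:
    """One HapMap phase III allele-frequency file -> marker_id/chrom/pos/freq."""
    with open(path) as fh:
        first = fh.readline()
    has_header = first.lstrip().startswith("rs#")
    if has_header:
        df = pd.read_csv(path, sep=r"\s+")
        cols = {c.lower(): c for c in df.columns}
        def pick(*names):
            for n in names:
                if n in cols:
                    return cols[n]
            raise ValueError(f"{path}: missing required column {names[0]!r}")
        df = df.rename(
            columns={
                pick("rs#"): "rs",
                pick("chrom"): "chrom",
                pick("pos"): "pos",
                pick("refallele_freq", "ref_freq"): "ref_freq",
                pick("otherallele_freq", "other_freq"): "other_freq",
            }
        )
    else:
        df = pd.read_csv(path, sep=r"\s+", header=None, names=_HAPMAP_SHORT_COLS)
    for c in ("ref_freq", "other_freq"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["pos"] = pd.to_numeric(df["pos"], errors="coerce")
    bad = (
        df["ref_freq"].isna()
        | df["other_freq"].isna()
        | df["pos"].isna()
        | ((df["ref_freq"] + df["other_freq"] - 1.0).abs() > 0.01)
    )
    if bad.any():
        logger.warning("%s: rejected %d malformed rows", path, int(bad.sum()))
        df = df[~bad]
    df["chrom"] = df["chrom"].astype(str).str.replace("^chr", "", regex=True)
    out = df[["rs", "chrom", "pos", "ref_freq"]].copy()
    out.columns = ["marker_id", "chrom", "pos", "freq"]
    return out.drop_duplicates("marker_id")


def read_hapmap_frequencies(files: Mapping[str, str]) -> FrequencyTable:
    """Merge per-population HapMap allele-frequency files by rs id.

    ``files`` maps population name -> path.  Only markers present in
    every file (after row validation) are kept; frequencies are of the
    file's reference allele, taken from the first file's orientation
    (strand and allele identity are not reconciled — the measures are
    allele-choice invariant).
    """
    if not files:
        raise ValueError("no input files")
    merged: pd.DataFrame | None = None
    for pop, path in files.items():
        one = _read_hapmap_one(path).rename(columns={"freq": f"freq_{pop}"})
        if merged is None:
            merged = one
        else:
            merged = merged.merge(
                one[["marker_id", f"freq_{pop}"]], on="marker_id", how="inner"
            )
    return FrequencyTable(merged.reset_index(drop=True), pop_names=list(files))


def filter_shared(table: FrequencyTable, max_missing: float = 0.10) -> FrequencyTable:
    """Keep markers typed in every population with missingness <= max_missing.

    A marker whose frequency is NaN in any population is dropped, as is
    any marker with ``missing_fraction`` strictly greater than
    ``max_missing`` ("over 10%" excluded; exactly 10% kept).
    """
    df = table.df
    keep = df["missing_fraction"].to_numpy(dtype=float) <= max_missing
    for pop in table.pop_names:
        keep &= df[f"freq_{pop}"].notna().to_numpy()
    if not keep.any():
        logger.warning("filter_shared: no markers remain")
    return FrequencyTable(df[keep].reset_index(drop=True), pop_names=table.pop_names)


# ----------------------------------------------------------------------
# scores, panels, genotypes, estimates, truth
# ----------------------------------------------------------------------

def write_scores(scores: MeasureScores, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# m1={scores.m1}\tlog_base={scores.log_base}\n")
        scores.df.to_csv(fh, sep="\t", index=False)


def read_scores(path) -> MeasureScores:
    m1, log_base = 0.8, "e"
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        meta = dict(kv.split("=", 1) for kv in first[1:].split())
        m1 = float(meta.get("m1", m1))
        log_base = meta.get("log_base", log_base)
    df = pd.read_csv(path, sep="\t", comment="#")
    df["chrom"] = df["chrom"].astype(str)
    measures = tuple(c for c in df.columns if f"rank_{c}" in df.columns)
    return MeasureScores(df=df, m1=m1, log_base=log_base, measures=measures)


def write_panel(panel: Panel, path, source_checksum: str | None = None) -> None:
    with open(path, "w") as fh:
        rule = panel.rule
        fh.write(
            f"# measure={panel.measure}\trule={rule.kind}\tvalue={rule.value}"
            f"\tmin_bp={rule.min_bp}\tsource_md5={source_checksum or 'NA'}\n"
        )
        panel.df.to_csv(fh, sep="\t", index=False)


def read_panel(path) -> Panel:
    measure, rule = "unknown", SelectionRule("all")
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        meta = dict(kv.split("=", 1) for kv in first[1:].split())
        measure = meta.get("measure", measure)
        value = meta.get("value", "None")
        rule = SelectionRule(
            meta.get("rule", "all"),
            None if value == "None" else float(value),
            int(meta.get("min_bp", 0)),
        )
    df = pd.read_csv(path, sep="\t", comment="#")
    df["chrom"] = df["chrom"].astype(str)
    return Panel(measure=measure, df=df, rule=rule)


def write_genotypes(G: GenotypeMatrix, path) -> None:
    G.to_dataframe().to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeMatrix:
    return GenotypeMatrix.from_dataframe(pd.read_csv(path, sep="\t", comment="#"))


def write_truth(truth: SimTruth, path) -> None:
    truth.to_dataframe().to_csv(path, sep="\t", index=False)


def read_truth(path) -> SimTruth:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SimTruth(
        sample_ids=df["sample_id"].to_numpy(dtype=object),
        q_true=df["q_true"].to_numpy(dtype=float),
    )


def write_estimates(est: AncestryEstimate, path, summary_path=None) -> None:
    est.to_dataframe().to_csv(path, sep="\t", index=False)
    if summary_path is not None:
        write_json(
            {
                "panel": est.panel,
                "n_markers": est.n_markers,
                "mean_q_hat": est.mean_q_hat,
                "sd_q_hat": est.sd_q_hat,
                "n_samples": int(len(est.sample_ids)),
                "n_all_missing": int(est.all_missing.sum()),
            },
            summary_path,
        )


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
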