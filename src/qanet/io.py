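"""Readers and writers for the pipeline's plain-text formats.

Matrices travel as TSV with a header row (feature rows, time-point columns
labelled in hours), sequences as FASTA, layouts/truth/calls as TSV tables,
and configuration/registry/summaries as JSON.
"""

from __future__ import annotations

import json
import os
from datetime import datetime, timezone

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from qanet import __version__
from qanet._errors import FormatError, StructuralError
from qanet.synth import ChipLayout, ChipSet, TruthLabels


def write_chipset(chipset: ChipSet, layout: ChipLayout, out_dir: str,
                  prefix: str = "intensities") -> list:
    """One TSV per experiment (rows features, columns hours)."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    cols = [f"{t:g}" for t in chipset.time_grid_hr]
    for i, exp in enumerate(chipset.experiments):
        df = pd.DataFrame(chipset.intensities[i].T, columns=cols,
                          index=pd.Index(layout.feature_ids, name="feature"))
        path = os.path.join(out_dir, f"{prefix}_{exp}.tsv")
        df.to_csv(path, sep="\t")
        paths.append(path)
    return paths


def read_chipset(paths: list, layout: ChipLayout,
                 experiments=None) -> ChipSet:
    """Read per-experiment TSVs back into a ChipSet."""
    mats, grid = [], None
    for path in paths:
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except Exception as exc:
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        if list(df.index) != list(layout.feature_ids):
            raise StructuralError(f"{path}: features do not match layout")
        times = np.asarray([float(c) for c in df.columns])
        if grid is None:
            grid = times
        elif not np.array_equal(grid, times):
            raise StructuralError(f"{path}: time grid differs between files")
        mats.append(df.to_numpy().T)
    exps = tuple(experiments) if experiments is not None else tuple(
        os.path.splitext(os.path.basename(p))[0].split("_")[-1] for p in paths)
    return ChipSet(np.stack(mats), grid, np.zeros(len(mats)), exps)


def write_layout(layout: ChipLayout, path: str):
    pd.DataFrame({
        "feature": list(layout.feature_ids),
        "gene": [layout.gene_of_feature.get(f, "") for f in layout.feature_ids],
        "negative_control": layout.negative_control_flags.astype(int),
        "spike": layout.spike_flags.astype(int),
    }).to_csv(path, sep="\t", index=False)


def read_layout(path: str) -> ChipLayout:
    df = pd.read_csv(path, sep="\t", dtype={"feature": str, "gene": str},
                     keep_default_na=False)
    gene_of = {f: g for f, g in zip(df["feature"], df["gene"]) if g}
    return ChipLayout(tuple(df["feature"]), gene_of,
                      df["negative_control"].to_numpy(dtype=bool),
                      df["spike"].to_numpy(dtype=bool))


def write_truth(truth: TruthLabels, path: str):
    truth.table.to_csv(path, sep="\t")


def read_truth(path: str) -> TruthLabels:
    return TruthLabels(pd.read_csv(path, sep="\t", index_col=0))


def write_fasta(sequences: dict, path: str):
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict:
    out = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise StructuralError(f"duplicate sequence id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_calls(callset, layout: ChipLayout, path: str):
    """Calls TSV: feature, gene, per-experiment flags and p-values, class."""
    rows = {"feature": list(callset.feature_ids),
            "gene": [layout.gene_of_feature.get(f, "")
                     for f in callset.feature_ids]}
    for exp, calls in callset.calls.items():
        rows[f"{exp}_up"] = calls.up.astype(int)
        rows[f"{exp}_down"] = calls.down.astype(int)
        rows[f"{exp}_p_upper"] = calls.p_upper
    rows["final_class"] = callset.final_class
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def provenance_record(command: str, config: dict) -> dict:
    return {
        "command": command,
        "qanet_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": config,
    }
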