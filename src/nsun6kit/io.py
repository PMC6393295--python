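"""File formats: FASTA sequences, TSV tables, JSON configs and results.

FASTA handling goes through Biopython.  Rate datasets and melting
curves use simple two-column TSV (``s_uM``/``v_uM_per_min`` and
``temp_C``/``a260``); rule sets, fit results and classification
results serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kinetics import MichaelisMentenParams, RateDataset
from .recognition import PanelResult, RuleSet
from .thermal import MeltingCurve, TmEstimate
from .trna import TRNARecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_rate_tsv",
    "write_rate_tsv",
    "read_melt_tsv",
    "write_melt_tsv",
    "load_ruleset_json",
    "dump_ruleset_json",
    "write_panel_result",
    "params_to_dict",
    "tm_to_dict",
]


def read_fasta(path: str | Path) -> list[TRNARecord]:
    """Read a (multi-)FASTA of tRNA sequences; T is normalized to U."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            TRNARecord(id=rec.id, sequence=str(rec.seq), source=f"fasta:{path}")
        )
    return records


def write_fasta(records: Iterable[TRNARecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.source)
        for rec in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def write_rate_tsv(data: RateDataset, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"s_uM": data.substrate_concs, "v_uM_per_min": data.rates}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_rate_tsv(
    path: str | Path, enzyme_conc_nM: float, noise_sd_rel: float = 0.0
) -> RateDataset:
    frame = pd.read_csv(path, sep="\t")
    return RateDataset(
        substrate_concs=tuple(frame["s_uM"].astype(float)),
        rates=tuple(frame["v_uM_per_min"].astype(float)),
        enzyme_conc_nM=enzyme_conc_nM,
        noise_sd_rel=noise_sd_rel,
    )


def write_melt_tsv(curve: MeltingCurve, path: str | Path) -> None:
    frame = pd.DataFrame(
        {"temp_C": curve.temperatures, "a260": curve.absorbance}
    )
    frame.to_csv(path, sep="\t", index=False)


def read_melt_tsv(path: str | Path) -> MeltingCurve:
    frame = pd.read_csv(path, sep="\t")
    return MeltingCurve(
        temperatures=tuple(frame["temp_C"].astype(float)),
        absorbance=tuple(frame["a260"].astype(float)),
        metadata={"source": str(path)},
    )


def load_ruleset_json(path: str | Path) -> RuleSet:
    with open(path) as handle:
        return RuleSet.from_dict(json.load(handle))


def dump_ruleset_json(rules: RuleSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        json.dump(rules.to_dict(), handle, indent=2)
        handle.write("\n")


def write_panel_result(result: PanelResult, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write a panel classification as TSV and JSON; returns the paths."""
    out_prefix = Path(out_prefix)
    tsv_path = out_prefix.with_suffix(".tsv")
    json_path = out_prefix.with_suffix(".json")
    frame = result.to_frame()
    frame.to_csv(tsv_path, sep="\t", index=False)
    payload = {
        "panel": result.panel_name,
        "ruleset": result.ruleset_name,
        "n_substrates": result.n_substrates,
        "n_non_substrates": result.n_non_substrates,
        "members": frame.to_dict(orient="records"),
    }
    with open(json_path, "w") as handle:
        json.dump(payload, handle, indent=2, default=_jsonable)
        handle.write("\n")
    return tsv_path, json_path


def params_to_dict(params: MichaelisMentenParams, diagnostics: dict | None = None) -> dict:
    out = {
        "kcat_per_min": params.kcat,
        "km_uM": params.km,
        "kcat_over_km_per_uM_per_min": params.kcat / params.km,
        "enzyme_conc_nM": params.enzyme_conc_nM,
    }
    if diagnostics:
        out["diagnostics"] = diagnostics
    return out


def tm_to_dict(estimate: TmEstimate) -> dict:
    return {
        "tm_C": round(estimate.tm_c, 1),
        "tm_C_full_precision": estimate.tm_c,
        "peak_height_AU_per_C": estimate.peak_height,
        "method": estimate.method,
    }


def _jsonable(obj):
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
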