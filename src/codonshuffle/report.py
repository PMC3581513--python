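"""Batch report generation: every statistic for every sequence, one bundle.

The report is a plain nested dict (JSON-serialisable) so identical inputs
and seed give byte-identical serialised output.  Per-sequence failures are
recorded in place of results rather than aborting the batch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import AnalysisError, cpg_positional_comparison
from .composition import (
    DINUCLEOTIDES,
    composition_variance,
    gc_vector,
    positional_dinucleotide_freqs,
    positional_nucleotide_freqs,
    relative_dinucleotide_bias,
)
from .enc import effective_number_of_codons
from .sequence import CodingSequence, SequenceError
from .shuffle import MODES, ShuffleSpec, run_shuffle_replicates


@dataclass(frozen=True)
class ReportConfig:
    seed: int = 0
    replicates: int = 1000
    modes: tuple[str, ...] = MODES
    threshold: float = 1.0
    swap_sweeps: int = 10
    estimator: str = "corrected"


def _mode_seed(master: int, seq_index: int, mode_index: int) -> int:
    ss = np.random.SeedSequence([master, seq_index, mode_index])
    return int(ss.generate_state(1)[0] % (2**31))


def _sequence_entry(cds: CodingSequence, i: int, config: ReportConfig) -> dict:
    f3 = positional_nucleotide_freqs(cds, 3)
    d23 = positional_dinucleotide_freqs(cds, 23)
    enc = effective_number_of_codons(cds, config.estimator)
    entry: dict = {
        "id": cds.id,
        "codon_count": cds.codon_count,
        "enc": enc.enc,
        "enc_class_means": {str(k): v for k, v in sorted(enc.class_means.items())},
        "third_position_freqs": f3.as_dict(),
        "variance": {
            "gc3": composition_variance(gc_vector(f3)),
            "n3": composition_variance(f3),
            "dn23": composition_variance(d23),
        },
        "rdb": {},
        "shuffle": [],
    }
    for pair in (23, 31):
        table = relative_dinucleotide_bias(cds, pair)
        entry["rdb"][str(pair)] = {
            d: (float(table.rdb[k]) if table.defined[k] else None)
            for k, d in enumerate(DINUCLEOTIDES)
        }
    for m, mode in enumerate(config.modes):
        spec = ShuffleSpec(
            mode=mode,
            replicates=config.replicates,
            seed=_mode_seed(config.seed, i, m),
            swap_sweeps=config.swap_sweeps,
            threshold=config.threshold,
            estimator=config.estimator,
        )
        summary = run_shuffle_replicates(cds, spec)
        entry["shuffle"].append(
            {
                "mode": summary.mode,
                "enc_original": summary.enc_original,
                "enc_mean": summary.enc_mean,
                "enc_sd": summary.enc_sd,
                "delta": summary.call.delta,
                "significant": summary.call.significant,
            }
        )
    return entry


def full_report(seqs: list[CodingSequence], config: ReportConfig | None = None) -> dict:
    """Compute the full per-sequence and panel-level report bundle."""
    if config is None:
        config = ReportConfig()
    if not seqs:
        raise ValueError("need at least one valid coding sequence")
    entries = []
    for i, cds in enumerate(seqs):
        try:
            entries.append(_sequence_entry(cds, i, config))
        except SequenceError as exc:
            entries.append({"id": cds.id, "error": str(exc)})
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config) | {"modes": list(config.modes)},
        "sequences": entries,
        "comparisons": {},
    }
    if len(seqs) >= 2:
        try:
            cpg = cpg_positional_comparison(seqs)
            report["comparisons"]["cpg_23_vs_31"] = {
                "mean_rdb_23": cpg.mean_a,
                "mean_rdb_31": cpg.mean_b,
                "sem_23": cpg.sem_a,
                "sem_31": cpg.sem_b,
                "p_value": cpg.p_value,
                "n_dropped": cpg.n_dropped,
            }
        except AnalysisError as exc:
            report["comparisons"]["cpg_23_vs_31"] = {"error": str(exc)}
    return report


def write_report_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_tables(report: dict) -> dict[str, pd.DataFrame]:
    """Flatten the bundle into TSV-ready tables (4-decimal rounding)."""
    seq_rows, shuffle_rows, rdb_rows = [], [], []
    for e in report["sequences"]:
        if "error" in e:
            seq_rows.append({"id": e["id"], "error": e["error"]})
            continue
        seq_rows.append(
            {
                "id": e["id"],
                "codon_count": e["codon_count"],
                "enc": round(e["enc"], 4),
                "var_gc3": round(e["variance"]["gc3"], 4),
                "var_n3": round(e["variance"]["n3"], 4),
                "var_dn23": round(e["variance"]["dn23"], 4),
            }
        )
        for s in e["shuffle"]:
            shuffle_rows.append(
                {
                    "id": e["id"],
                    "mode": s["mode"],
                    "enc_original": round(s["enc_original"], 4),
                    "enc_mean": round(s["enc_mean"], 4),
                    "enc_sd": round(s["enc_sd"], 4),
                    "delta": round(s["delta"], 4),
                    "significant": s["significant"],
                }
            )
        for pair, table in e["rdb"].items():
            for d, v in table.items():
                rdb_rows.append(
                    {
                        "id": e["id"],
                        "pair": pair,
                        "state": d,
                        "rdb": round(v, 4) if v is not None else "",
                    }
                )
    return {
        "sequences": pd.DataFrame(seq_rows),
        "shuffle": pd.DataFrame(shuffle_rows),
        "rdb": pd.DataFrame(rdb_rows),
    }


def write_report_tsv(report: dict, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in report_tables(report).items():
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
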