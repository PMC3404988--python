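"""Readers and writers for the plain-text dialects used by the pipeline.

* multi-FASTA for references / clones (the description may carry the source
  clade as ``clade=X``);
* a YAML catalogue of primers and enzymes;
* delimited peak tables (``sample_id, month, size_bp, height, qv``; one row
  per peak, the QV repeated per sample);
* TSV outputs: T-RF prediction tables, profile matrices, month summaries,
  isotope/TP tables.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import ConfigError, InputError
from .seqlib import Enzyme, Primer, SeqRecord, TRFPrediction
from .stats import IsotopeRecord, MonthComparison, TrophicPosition
from .trflp import Chromatogram, Peak, Profile

_CLADE_RE = re.compile(r"clade=(\S+)")


def read_fasta(path: "str | Path") -> list[SeqRecord]:
    """Read a multi-FASTA; a ``clade=X`` token in the description is parsed."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"cannot read FASTA: {path} does not exist")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _CLADE_RE.search(rec.description)
        records.append(
            SeqRecord(id=rec.id, seq=str(rec.seq), clade_label=m.group(1) if m else None)
        )
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SeqRecord], path: "str | Path") -> None:
    """Write records as multi-FASTA, embedding clade labels as ``clade=X``."""
    bio = []
    for r in records:
        desc = f"clade={r.clade_label}" if r.clade_label else ""
        bio.append(BioSeqRecord(Seq(r.seq), id=r.id, description=desc))
    SeqIO.write(bio, str(Path(path)), "fasta")


def load_catalogue(path: "str | Path") -> tuple[dict[str, Primer], dict[str, Enzyme]]:
    """Load primer and enzyme definitions from a YAML catalogue.

    Schema::

        primers:
          trbcL-F: {sequence: CTKGC..., labeled: true}
        enzymes:
          TaiI: {recognition: ACGT, cut_offset: 4}
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"catalogue file {path} does not exist")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed catalogue {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"catalogue {path} must be a mapping")
    primers: dict[str, Primer] = {}
    for name, spec in (data.get("primers") or {}).items():
        try:
            primers[name] = Primer(
                name=name, seq=spec["sequence"], labeled=bool(spec.get("labeled", False))
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"primer {name!r}: missing field {exc}") from exc
    enzymes: dict[str, Enzyme] = {}
    for name, spec in (data.get("enzymes") or {}).items():
        try:
            enzymes[name] = Enzyme(
                name=name,
                recognition=spec["recognition"],
                cut_offset=int(spec["cut_offset"]),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"enzyme {name!r}: missing field {exc}") from exc
    return primers, enzymes


def write_predictions(predictions: Sequence[TRFPrediction], path: "str | Path") -> None:
    """TSV of T-RF predictions: clade_label, trf_lengths, category_label."""
    rows = [
        {
            "clade_label": p.clade_label,
            "trf_lengths": ",".join(str(l) for l in sorted(p.trf_lengths)),
            "category_label": p.category_label,
        }
        for p in predictions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_predictions(path: "str | Path") -> list[TRFPrediction]:
    """Read a prediction TSV back into (merged) T-RF categories."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"cannot read predictions: {path} does not exist")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"clade_label", "trf_lengths", "category_label"}
    if missing := required - set(df.columns):
        raise InputError(f"prediction table {path} lacks columns {sorted(missing)}")
    merged: dict[str, set[int]] = {}
    clades: dict[str, str] = {}
    for _, row in df.iterrows():
        lengths = {int(x) for x in str(row["trf_lengths"]).split(",")}
        merged.setdefault(row["category_label"], set()).update(lengths)
        clades.setdefault(row["category_label"], row["clade_label"])
    return [
        TRFPrediction(
            clade_label=clades[cat], trf_lengths=frozenset(ls), category_label=cat
        )
        for cat, ls in sorted(merged.items())
    ]


PEAK_COLUMNS = ["sample_id", "month", "size_bp", "height", "qv"]


def read_peak_table(path: "str | Path") -> tuple[list[Chromatogram], list[int]]:
    """Parse a delimited peak table into per-sample chromatograms.

    The delimiter is sniffed (comma or tab).  Rows with unparsable numbers
    are rejected; their 1-based row numbers are returned alongside the
    chromatograms.  A sample whose rows disagree on QV or month is an error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"cannot read peak table: {path} does not exist")
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if missing := set(PEAK_COLUMNS) - set(df.columns):
        raise InputError(f"peak table {path} lacks columns {sorted(missing)}")

    rejected: list[int] = []
    parsed = []
    for i, row in df.iterrows():
        try:
            size = float(row["size_bp"])
            height = float(row["height"])
            qv = float(row["qv"])
            if size <= 0 or height < 0 or qv < 0:
                raise ValueError
        except (TypeError, ValueError):
            rejected.append(int(i) + 2)  # 1-based, counting the header line
            continue
        parsed.append((str(row["sample_id"]), str(row["month"]), size, height, qv))

    by_sample: dict[str, dict] = {}
    for sample_id, month, size, height, qv in parsed:
        entry = by_sample.setdefault(
            sample_id, {"month": month, "qv": qv, "peaks": []}
        )
        if entry["qv"] != qv:
            raise InputError(
                f"sample {sample_id!r}: inconsistent QV values "
                f"({entry['qv']} vs {qv})"
            )
        if entry["month"] != month:
            raise InputError(f"sample {sample_id!r}: inconsistent collection month")
        entry["peaks"].append(Peak(size=size, height=height))
    chroms = [
        Chromatogram(
            sample_id=s,
            collection_month=e["month"],
            qv=e["qv"],
            peaks=tuple(e["peaks"]),
        )
        for s, e in by_sample.items()
    ]
    return chroms, rejected


def write_peak_table(
    chroms: Iterable[Chromatogram], path: "str | Path", sep: str = ","
) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "month": c.collection_month,
            "size_bp": p.size,
            "height": p.height,
            "qv": c.qv,
        }
        for c in chroms
        for p in c.peaks
    ]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, sep=sep, index=False)


def write_profiles(profiles: Sequence[Profile], path: "str | Path") -> None:
    """Profile matrix: one row per sample, percent per category + unassigned."""
    categories = sorted({c for p in profiles for c in p.ra})
    rows = []
    for p in profiles:
        row = {"sample_id": p.sample_id, "month": p.collection_month}
        for c in categories:
            row[c] = p.ra.get(c, 0.0)
        row["unassigned"] = p.unassigned_pct
        rows.append(row)
    cols = ["sample_id", "month", *categories, "unassigned"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_profiles(path: "str | Path") -> list[Profile]:
    path = Path(path)
    if not path.exists():
        raise InputError(f"cannot read profiles: {path} does not exist")
    df = pd.read_csv(path, sep="\t")
    if missing := {"sample_id", "month", "unassigned"} - set(df.columns):
        raise InputError(f"profile table {path} lacks columns {sorted(missing)}")
    categories = [c for c in df.columns if c not in ("sample_id", "month", "unassigned")]
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            Profile(
                sample_id=str(row["sample_id"]),
                collection_month=str(row["month"]),
                ra={c: float(row[c]) for c in categories},
                unassigned_pct=float(row["unassigned"]),
            )
        )
    return profiles


ISOTOPE_COLUMNS = ["specimen_id", "group", "d15n_glu", "d15n_phe"]


def read_isotopes(path: "str | Path") -> list[IsotopeRecord]:
    """Read the per-specimen amino-acid d15N table (CSV or TSV)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"cannot read isotope table: {path} does not exist")
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, pd.errors.ParserError, csv.Error) as exc:
        raise InputError(f"cannot parse isotope table {path}: {exc}") from exc
    if missing := set(ISOTOPE_COLUMNS) - set(df.columns):
        raise InputError(f"isotope table {path} lacks columns {sorted(missing)}")
    return [
        IsotopeRecord(
            specimen_id=str(row["specimen_id"]),
            group_label=str(row["group"]),
            d15n_glu=float(row["d15n_glu"]),
            d15n_phe=float(row["d15n_phe"]),
        )
        for _, row in df.iterrows()
    ]


def write_isotopes(records: Iterable[IsotopeRecord], path: "str | Path") -> None:
    rows = [
        {
            "specimen_id": r.specimen_id,
            "group": r.group_label,
            "d15n_glu": r.d15n_glu,
            "d15n_phe": r.d15n_phe,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ISOTOPE_COLUMNS).to_csv(path, index=False)


def write_tp_table(results: dict[str, TrophicPosition], path: "str | Path") -> None:
    """TP table with full-precision and one-decimal display columns."""
    rows = []
    for group, tp in results.items():
        rows.append(
            {
                "group": group,
                "n": tp.n,
                "tp": tp.tp,
                "tp_display": tp.tp_display,
                "sd": "" if tp.sd is None else tp.sd,
                "sd_sample": "" if tp.sd_sample is None else tp.sd_sample,
                "sd_population": "" if tp.sd_population is None else tp.sd_population,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_test_result(result: MonthComparison, path: "str | Path") -> None:
    pd.DataFrame(
        [
            {
                "category": result.category,
                "month_a": result.month_a,
                "month_b": result.month_b,
                "n_a": result.n_a,
                "n_b": result.n_b,
                "low_power": result.low_power,
                "statistic": result.test.statistic,
                "p_hat": result.test.p_hat,
                "p_value": result.test.p_value,
                "n_perm": result.test.n_perm,
                "exhaustive": result.test.exhaustive,
            }
        ]
    ).to_csv(path, sep="\t", index=False)


def write_run_metadata(path: "str | Path", **params: object) -> None:
    """JSON sidecar recording every threshold and seed used (audit trail)."""
    Path(path).write_text(json.dumps(params, indent=2, sort_keys=True, default=str) + "\n")
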