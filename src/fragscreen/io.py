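"""Readers and writers for the on-disk formats shared by all modules.

Formats (all plain text):

* SMILES libraries: ``SMILES<whitespace>identifier`` per line, ``#``
  comments and blank lines skipped (see :mod:`fragscreen.chem`).
* Benchmark tree: ``targets.tsv``, ``identity.tsv``, ``manifest.json``
  and one directory per target with ``actives.smi``, ``decoys.smi`` and
  ``templates.tsv``.
* Ranked screens: TSV of rank, ligand id, raw score, label and any
  extra per-entry columns (winning method, best template).
* Fingerprint dumps: TSV of identifier, scheme, length and the sorted
  set-bit indices rendered 1-based.
* Precomputed descriptor tables: CSV with an identifier column followed
  by 881 binary key columns in key order.

Floats are serialized with ``repr`` so every file round-trips exactly.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .benchmark import Benchmark, BenchmarkTarget
from .chem import SmilesRecord, read_smiles_file, write_smiles_file
from .fingerprints import BitFingerprint, CombinedFingerprint, Scheme
from .metrics import RankedScreen
from .pockets import TargetProfile, TemplatePocketRecord

TEMPLATE_COLUMNS = ("template_id", "tm_score", "aligned_fraction",
                    "seq_identity", "rank_score", "pocket_residues",
                    "template_ligand_smiles")


# ---------------------------------------------------------------------------
# Template metadata
# ---------------------------------------------------------------------------

def write_templates_tsv(candidates: list[TemplatePocketRecord], path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(TEMPLATE_COLUMNS) + "\n")
        for rec in candidates:
            ligands = ";".join(lig.smiles for lig in rec.template_ligands)
            handle.write("\t".join([
                rec.template_id, repr(rec.tm_score),
                repr(rec.aligned_fraction), repr(rec.seq_identity),
                repr(rec.rank_score), rec.pocket_residues, ligands,
            ]) + "\n")


def read_templates_tsv(path) -> list[TemplatePocketRecord]:
    records = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != TEMPLATE_COLUMNS:
            raise ValueError(f"{path}: unexpected template columns {header}")
        for line in handle:
            (tid, tm, cov, seqid, rank, residues,
             ligands) = line.rstrip("\n").split("\t")
            template_ligands = [
                SmilesRecord(smiles, f"{tid}_L{k}")
                for k, smiles in enumerate(ligands.split(";"))
                if smiles
            ]
            records.append(TemplatePocketRecord(
                template_id=tid, pocket_residues=residues,
                tm_score=float(tm), aligned_fraction=float(cov),
                seq_identity=float(seqid), rank_score=float(rank),
                template_ligands=template_ligands))
    return records


# ---------------------------------------------------------------------------
# Benchmark tree
# ---------------------------------------------------------------------------

def write_benchmark(benchmark: Benchmark, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "targets.tsv", "w") as handle:
        handle.write("target_id\tfamily\tsequence\n")
        for t in benchmark.targets:
            family = "" if t.family is None else str(t.family)
            handle.write(f"{t.target_id}\t{family}\t{t.profile.sequence}\n")
    benchmark.identity.to_csv(out / "identity.tsv", sep="\t",
                              float_format=None)
    with open(out / "manifest.json", "w") as handle:
        json.dump({"spec": benchmark.spec}, handle, indent=1, sort_keys=True)
        handle.write("\n")
    for t in benchmark.targets:
        tdir = out / t.target_id
        tdir.mkdir(exist_ok=True)
        write_smiles_file(tdir / "actives.smi", t.actives)
        write_smiles_file(tdir / "decoys.smi", t.decoys)
        write_templates_tsv(t.candidates, tdir / "templates.tsv")


def load_benchmark(in_dir, seqid_cutoff: float | None = None,
                   pooled_composition: bool = False) -> Benchmark:
    root = Path(in_dir)
    targets_table = pd.read_csv(root / "targets.tsv", sep="\t",
                                dtype={"target_id": str})
    identity = pd.read_csv(root / "identity.tsv", sep="\t", index_col=0)
    identity.index = identity.index.astype(str)
    identity.columns = identity.columns.astype(str)
    manifest_path = root / "manifest.json"
    spec = None
    if manifest_path.exists():
        with open(manifest_path) as handle:
            spec = json.load(handle).get("spec")
    targets = []
    for _, row in targets_table.iterrows():
        tid = str(row["target_id"])
        tdir = root / tid
        candidates = read_templates_tsv(tdir / "templates.tsv")
        profile = TargetProfile.from_candidates(
            tid, str(row["sequence"]), candidates,
            seqid_cutoff=seqid_cutoff,
            pooled_composition=pooled_composition)
        family = row.get("family")
        family = None if pd.isna(family) else int(family)
        targets.append(BenchmarkTarget(
            profile=profile,
            actives=read_smiles_file(tdir / "actives.smi"),
            decoys=read_smiles_file(tdir / "decoys.smi"),
            candidates=candidates,
            family=family))
    return Benchmark(targets=targets, identity=identity, spec=spec)


# ---------------------------------------------------------------------------
# Ranked screens
# ---------------------------------------------------------------------------

def _flat_info(entry) -> dict[str, object]:
    """Entry info with nested dicts flattened to ``key.subkey`` columns
    (e.g. the per-method precisions of a meta-combined screen)."""
    flat: dict[str, object] = {}
    for key, value in entry.info.items():
        if isinstance(value, dict):
            for sub, subval in value.items():
                flat[f"{key}.{sub}"] = subval
        else:
            flat[key] = value
    return flat


def write_ranked_screen(screen: RankedScreen, path) -> None:
    extra_keys: list[str] = []
    for entry in screen.entries:
        for key in _flat_info(entry):
            if key not in extra_keys:
                extra_keys.append(key)
    with open(path, "w") as handle:
        handle.write(f"# target_id={screen.target_id}\n")
        cols = ["rank", "ligand_id", "score", "label"] + extra_keys
        handle.write("\t".join(cols) + "\n")
        for rank, entry in enumerate(screen.entries, start=1):
            label = "" if entry.label is None else str(entry.label)
            row = [str(rank), entry.ligand_id, repr(entry.score), label]
            flat = _flat_info(entry)
            row += [str(flat.get(k, "")) for k in extra_keys]
            handle.write("\t".join(row) + "\n")


def read_ranked_screen(path) -> RankedScreen:
    with open(path) as handle:
        first = handle.readline().strip()
        if not first.startswith("# target_id="):
            raise ValueError(f"{path}: missing target_id header")
        target_id = first.split("=", 1)[1]
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        ids, scores, labels, infos = [], [], [], []
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[idx["ligand_id"]])
            scores.append(float(parts[idx["score"]]))
            raw_label = parts[idx["label"]]
            labels.append(int(raw_label) if raw_label else None)
            infos.append({
                k: parts[i] for k, i in idx.items()
                if k not in ("rank", "ligand_id", "score", "label")
                and parts[i]
            })
    return RankedScreen.from_scores(target_id, ids, scores, labels, infos)


# ---------------------------------------------------------------------------
# Fingerprint dumps and descriptor ingestion
# ---------------------------------------------------------------------------

def write_fingerprint_dump(
    rows: list[tuple[str, BitFingerprint | CombinedFingerprint]], path
) -> None:
    """TSV of identifier, scheme, length, sorted set bits (1-based)."""
    with open(path, "w") as handle:
        handle.write("identifier\tscheme\tlength\tset_bits\n")
        for identifier, fp in rows:
            scheme = fp.scheme.value if isinstance(fp, BitFingerprint) \
                else "combined:" + "+".join(s.value for s in fp.blocks)
            bits = ",".join(str(b + 1) for b in sorted(fp.set_bits))
            handle.write(f"{identifier}\t{scheme}\t{fp.length}\t{bits}\n")


def read_descriptor_table(path, id_column: str | None = None
                          ) -> dict[str, BitFingerprint]:
    """Ingest a precomputed 881-column binary descriptor CSV.

    The first (or named) column is the molecule identifier; the remaining
    881 columns are the key values in key order. Values above zero set
    the corresponding bit.
    """
    table = pd.read_csv(path)
    if id_column is None:
        id_column = table.columns[0]
    keys = [c for c in table.columns if c != id_column]
    if len(keys) != 881:
        raise ValueError(
            f"descriptor table must have 881 key columns, got {len(keys)}")
    out: dict[str, BitFingerprint] = {}
    values = table[keys].to_numpy()
    for i, mol_id in enumerate(table[id_column].astype(str)):
        bits = frozenset(int(j) for j in np.nonzero(values[i] > 0)[0])
        out[mol_id] = BitFingerprint(scheme=Scheme.PUBCHEM, length=881,
                                     set_bits=bits)
    return out


# ---------------------------------------------------------------------------
# Metrics report
# ---------------------------------------------------------------------------

def write_metrics_report(aggregated: dict, path) -> None:
    """Per-target metric TSV preceded by a ``#``-prefixed summary block."""
    summary = aggregated["summary"]
    table: pd.DataFrame = aggregated["per_target"]
    with open(path, "w") as handle:
        for key in sorted(summary):
            val = summary[key]
            if isinstance(val, float) and not math.isnan(val):
                handle.write(f"# {key}\t{val:.6g}\n")
            else:
                handle.write(f"# {key}\t{val}\n")
        handle.write("\t".join(str(c) for c in table.columns) + "\n")
        for _, row in table.iterrows():
            handle.write("\t".join(str(v) for v in row.to_list()) + "\n")
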