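"""Chunked end-to-end pipeline driver.

Runs preparation, fragment search, combination classification, graph
assembly, PNP annotation and reporting as a plain sequential file-based
task chain: each stage reads its declared input files and writes its
outputs, so a run is resumable — stages whose outputs already exist are
skipped, and deleting one stage's output recomputes only that stage (and
whatever follows it is already on disk). Chunking plus the locked
identity-key store make chunked and unchunked runs produce the same
surviving molecules regardless of processing order.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml
from . import classify, fcg, fragments, metrics, pnp, prep


@dataclass
class RunManifest:
    """Bookkeeping for one pipeline run: per-stage molecule counts and the
    percentage remaining relative to the initial input."""

    dataset: str
    chunk_size: int
    counts: dict[str, int] = field(default_factory=dict)
    stages_run: list[str] = field(default_factory=list)
    paths: dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, count: int, ran: bool) -> None:
        self.counts[stage] = count
        if ran:
            self.stages_run.append(stage)

    def percentages(self) -> dict[str, float]:
        initial = self.counts.get("input", 0)
        if not initial:
            return {}
        return {k: 100.0 * v / initial for k, v in self.counts.items()}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "dataset": self.dataset,
                    "chunk_size": self.chunk_size,
                    "counts": self.counts,
                    "percent_of_input": {
                        k: round(v, 2) for k, v in self.percentages().items()
                    },
                    "stages_run": self.stages_run,
                    "paths": self.paths,
                },
                fh,
                sort_keys=False,
            )


def chunk_input(path: str | Path, size: int, fmt: str, out_dir: str | Path) -> list[Path]:
    """Split an input file into record-preserving chunks of ``size``."""
    if size < 1:
        raise ValueError("chunk size must be >= 1")
    path, out_dir = Path(path), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chunks: list[Path] = []

    def flush(buf: list[str], ext: str) -> None:
        cpath = out_dir / f"{path.stem}_chunk{len(chunks):04d}{ext}"
        with open(cpath, "w") as fh:
            fh.writelines(buf)
        chunks.append(cpath)

    if fmt == "smiles":
        buf: list[str] = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                buf.append(line if line.endswith("\n") else line + "\n")
                if len(buf) == size:
                    flush(buf, path.suffix or ".smi")
                    buf = []
        if buf:
            flush(buf, path.suffix or ".smi")
    elif fmt == "sdf":
        buf, record, n = [], [], 0
        with open(path) as fh:
            for line in fh:
                record.append(line)
                if line.strip() == "$$$$":
                    buf.extend(record)
                    record = []
                    n += 1
                    if n == size:
                        flush(buf, ".sdf")
                        buf, n = [], 0
        if record:  # trailing record without terminator
            buf.extend(record)
        if buf:
            flush(buf, ".sdf")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return chunks


@dataclass
class PipelineConfig:
    """File-level configuration of one run (see ``run.yaml`` docs)."""

    molecules: str
    molecules_format: str = "smiles"
    fragments: str = ""
    fragments_format: str = "smiles"
    out_dir: str = "fragcomb_run"
    dataset: str = "dataset"
    chunk_size: int = 5000
    excluded_fragments: tuple[str, ...] = ("benzene",)
    reference_dir: Optional[str] = None  # processed NP run to compare against
    with_fcp: bool = False
    filters: prep.FilterConfig = field(default_factory=prep.FilterConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "filters" in data:
            data["filters"] = prep.FilterConfig(**data["filters"])
        if "excluded_fragments" in data:
            data["excluded_fragments"] = tuple(data["excluded_fragments"])
        return cls(**data)


def _load_sdf_records(path: Path) -> list[prep.MoleculeRecord]:
    return [r for r in prep.load_molecules(path, "sdf") if r.status == "passed"]


def run_pipeline(cfg: PipelineConfig) -> RunManifest:
    """Execute the full task chain for one dataset.

    Stage order: fragment preparation, chunked molecule preparation with
    cross-chunk dedup, optional reference-structure removal, fragment
    search, combination classification, FCG assembly, optional PNP
    annotation, report. Aborts with the failing stage's name on error.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg.dataset, cfg.chunk_size)
    stage = "init"
    try:
        # --- fragments -----------------------------------------------------
        stage = "prep_fragments"
        frag_sdf = out / "prepared_fragments.sdf"
        ran = not frag_sdf.exists()
        if ran:
            recs = list(prep.load_molecules(cfg.fragments, cfg.fragments_format))
            prepared = list(prep.prepare_records(recs, cfg.filters, mode="fragments"))
            prep.write_sdf(prepared, frag_sdf)
            prep.write_log_tsv(prepared, out / "prepared_fragments_log.tsv")
        frag_records = fragments.prepare_fragments(
            [(r.record_id, r.mol) for r in _load_sdf_records(frag_sdf)]
        )
        frag_records = [
            f for f in frag_records if f.fragment_id not in cfg.excluded_fragments
        ]
        manifest.record(stage, len(frag_records), ran)
        manifest.paths[stage] = str(frag_sdf)

        # --- molecules, chunked -------------------------------------------
        stage = "prep_molecules"
        mol_sdf = out / "prepared_molecules.sdf"
        n_input = sum(
            1 for _ in prep.load_molecules(cfg.molecules, cfg.molecules_format)
        )
        manifest.record("input", n_input, False)
        ran = not mol_sdf.exists()
        if ran:
            chunk_dir = out / "chunks"
            if chunk_dir.exists():
                shutil.rmtree(chunk_dir)
            chunks = chunk_input(
                cfg.molecules, cfg.chunk_size, cfg.molecules_format, chunk_dir
            )
            store = prep.KeyStore(out / "dedup_reference.txt")
            all_records = []
            for chunk in chunks:
                recs = list(prep.load_molecules(chunk, cfg.molecules_format))
                all_records.extend(
                    prep.prepare_records(recs, cfg.filters, mode="molecules", store=store)
                )
            prep.write_sdf(all_records, mol_sdf)
            prep.write_log_tsv(all_records, out / "prepared_molecules_log.tsv")
        mol_records = _load_sdf_records(mol_sdf)
        manifest.record(stage, len(mol_records), ran)
        manifest.paths[stage] = str(mol_sdf)

        # --- optional removal of reference (NP) structures ------------------
        if cfg.reference_dir is not None:
            stage = "remove_reference_duplicates"
            filtered_sdf = out / "molecules_no_reference.sdf"
            ran = not filtered_sdf.exists()
            if ran:
                ref_sdf = Path(cfg.reference_dir) / "prepared_molecules.sdf"
                ref_keys = set()
                for rr in prep.load_molecules(ref_sdf, "sdf"):
                    if rr.status == "passed" and rr.mol.HasProp("identity_key"):
                        ref_keys.add(rr.mol.GetProp("identity_key"))
                kept = []
                for r in mol_records:
                    key = r.mol.GetProp("identity_key") if r.mol.HasProp("identity_key") else None
                    if key in ref_keys:
                        r.fail("filtered", "reference_duplicate")
                    else:
                        kept.append(r)
                prep.write_sdf(kept, filtered_sdf)
            mol_records = _load_sdf_records(filtered_sdf)
            manifest.record(stage, len(mol_records), ran)

        for r in mol_records:
            if r.mol.HasProp("identity_key"):
                r.identity_key = r.mol.GetProp("identity_key")

        # --- search ---------------------------------------------------------
        stage = "search"
        hits_tsv = out / "hits.tsv"
        ran = not hits_tsv.exists()
        if ran:
            all_hits = []
            for r in mol_records:
                all_hits.extend(fragments.search_fragments(r, frag_records))
            fragments.write_hits_tsv(all_hits, hits_tsv)
        hits_by_mol = fragments.read_hits_tsv(hits_tsv)
        manifest.record(stage, len(hits_by_mol), ran)
        manifest.paths[stage] = str(hits_tsv)

        # --- classify -------------------------------------------------------
        stage = "classify"
        combos_tsv = out / "combinations.tsv"
        ran = not combos_tsv.exists()
        rec_index = {r.record_id: r for r in mol_records}
        if ran:
            all_combos = []
            for mid, hits in sorted(hits_by_mol.items()):
                if len(hits) < 2 or mid not in rec_index:
                    continue
                all_combos.extend(
                    classify.classify_molecule(rec_index[mid], hits, cfg.filters)
                )
            classify.write_combinations_tsv(all_combos, combos_tsv)
        combos_by_mol = classify.read_combinations_tsv(combos_tsv, hits_by_mol)
        manifest.record(stage, len(combos_by_mol), ran)
        manifest.paths[stage] = str(combos_tsv)

        # --- fcg ------------------------------------------------------------
        stage = "fcg"
        graph_dir = out / "graphs"
        ran = not (graph_dir / "fcg_index.tsv").exists()
        if ran:
            graphs = []
            for mid, combos in sorted(combos_by_mol.items()):
                if mid not in rec_index:
                    continue
                graphs.extend(
                    fcg.build_fcgs(rec_index[mid], combos, cfg.filters, frag_records)
                )
            fcg.write_fcgs(graphs, graph_dir)
        all_graphs = fcg.read_fcgs(graph_dir)
        manifest.record(stage, len({g.molecule_id for g in all_graphs}), ran)
        manifest.paths[stage] = str(graph_dir)

        # --- pnp ------------------------------------------------------------
        verdicts = None
        if cfg.reference_dir is not None:
            stage = "pnp"
            verdict_tsv = out / "verdicts.tsv"
            ran = not verdict_tsv.exists()
            ref_graphs = fcg.read_fcgs(Path(cfg.reference_dir) / "graphs")
            ref_set = pnp.ReferenceGraphSet.build(ref_graphs, cfg.with_fcp)
            verdicts = pnp.annotate_dataset(all_graphs, ref_set, cfg.with_fcp)
            if ran:
                pnp.write_verdicts_tsv(verdicts, verdict_tsv)
            manifest.record(
                stage, sum(1 for v in verdicts if v.molecule_label == "pnp"), ran
            )
            manifest.paths[stage] = str(verdict_tsv)

        # --- report ----------------------------------------------------------
        stage = "report"
        report_dir = out / "report"
        ran = not report_dir.exists()
        graphs_by_mol: dict[str, list] = {}
        for g in all_graphs:
            graphs_by_mol.setdefault(g.molecule_id, []).append(g)
        metrics.attach_hits(graphs_by_mol, hits_by_mol)
        summary = metrics.summarize_dataset(mol_records, graphs_by_mol, verdicts)
        if ran:
            metrics.write_summary(summary, report_dir)
        manifest.record(stage, len(summary.per_molecule), ran)
        manifest.paths[stage] = str(report_dir)

        manifest.write(out / "manifest.yaml")
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
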