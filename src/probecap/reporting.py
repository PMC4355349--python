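"""Run outputs: probe tables, cluster file, non-redundant set and summaries.

A completed run emits exactly six files::

    probe_run1_summary       per-stage counts after primary design
    probe_run2_summary       per-stage counts after rescue
    probe_file1              TSV of primary probes
    probe_file2              TSV of all probes (both generations)
    core_cluster.txt         .clstr-style clustering of the input
    probe_non_redundant.txt  duplicate-free probe set

plus a machine-readable ``run_manifest.txt`` outside that set.  Probe TSVs
share one documented column order; summaries are two-column TSVs with a
stable key order so runs are byte-reproducible.
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .cluster import Cluster, write_clstr
from .probe_primary import Probe

PROBE_COLUMNS = (
    "probe_id",
    "cluster_id",
    "stage",
    "source_record",
    "offset",
    "seq",
    "gc",
    "tm",
    "coverage",
    "cycles",
)

OUTPUT_FILES = (
    "probe_run1_summary",
    "probe_run2_summary",
    "probe_file1",
    "probe_file2",
    "core_cluster.txt",
    "probe_non_redundant.txt",
)


@dataclass(frozen=True)
class ProbeRunSummary:
    """Per-stage counts: clusters covered, probes emitted, rejection tallies."""

    stage: str  # run1 | run2
    clusters_total: int
    clusters_with_probes: int
    probes_emitted: int
    probes_per_cluster_histogram: dict[int, int] = field(default_factory=dict)
    filter_rejections: dict[str, int] = field(default_factory=dict)


def nonredundant(probes: Sequence[Probe]) -> list[Probe]:
    """Collapse exact duplicate probe sequences to the first occurrence.

    The survivor records the cluster ids of collapsed duplicates in
    ``extra_cluster_ids`` (stable order, deduplicated, own cluster excluded).
    """
    by_seq: dict[str, int] = {}
    survivors: list[Probe] = []
    extras: list[list[int]] = []
    for p in probes:
        if p.seq in by_seq:
            i = by_seq[p.seq]
            keeper = survivors[i]
            if p.cluster_id != keeper.cluster_id and p.cluster_id not in extras[i]:
                extras[i].append(p.cluster_id)
        else:
            by_seq[p.seq] = len(survivors)
            survivors.append(p)
            extras.append(list(p.extra_cluster_ids))
    return [
        Probe(
            p.probe_id,
            p.cluster_id,
            p.seq,
            p.source_record,
            p.offset,
            p.stage,
            p.gc,
            p.tm,
            p.cycles,
            p.coverage,
            tuple(extra),
        )
        for p, extra in zip(survivors, extras)
    ]


def summarize(
    stage: str,
    clusters: Sequence[Cluster],
    probes: Sequence[Probe],
    filter_rejections: Mapping[str, int] | None = None,
) -> ProbeRunSummary:
    """Count clusters with probes and probes per cluster for one stage."""
    if stage not in ("run1", "run2"):
        raise ValueError("stage must be 'run1' or 'run2'")
    known = {c.cluster_id for c in clusters}
    per_cluster: dict[int, int] = {c.cluster_id: 0 for c in clusters}
    for p in probes:
        if p.cluster_id not in known:
            raise ValueError(f"probe {p.probe_id} references unknown cluster {p.cluster_id}")
        per_cluster[p.cluster_id] += 1
    hist: dict[int, int] = {}
    for n in per_cluster.values():
        hist[n] = hist.get(n, 0) + 1
    return ProbeRunSummary(
        stage=stage,
        clusters_total=len(clusters),
        clusters_with_probes=sum(1 for n in per_cluster.values() if n > 0),
        probes_emitted=len(probes),
        probes_per_cluster_histogram=dict(sorted(hist.items())),
        filter_rejections=dict(sorted((filter_rejections or {}).items())),
    )


def _probe_rows(probes: Sequence[Probe]) -> str:
    lines = ["\t".join(PROBE_COLUMNS) + "\n"]
    for p in probes:
        cov = "NA" if p.coverage is None else str(p.coverage)
        lines.append(
            f"{p.probe_id}\t{p.cluster_id}\t{p.stage}\t{p.source_record}\t"
            f"{p.offset}\t{p.seq}\t{p.gc:.3f}\t{p.tm:.3f}\t{cov}\t{p.cycles}\n"
        )
    return "".join(lines)


def _summary_text(s: ProbeRunSummary) -> str:
    lines = [
        "metric\tvalue\n",
        f"stage\t{s.stage}\n",
        f"clusters_total\t{s.clusters_total}\n",
        f"clusters_with_probes\t{s.clusters_with_probes}\n",
        f"probes_emitted\t{s.probes_emitted}\n",
    ]
    for n, c in s.probes_per_cluster_histogram.items():
        lines.append(f"clusters_with_{n}_probes\t{c}\n")
    for reason, c in s.filter_rejections.items():
        lines.append(f"rejected_{reason}\t{c}\n")
    return "".join(lines)


def write_probe_fasta(probes: Sequence[Probe], path: str | Path) -> None:
    """Optional FASTA export of probe sequences."""
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.probe_id}\n{p.seq}\n")


def write_outputs(
    run_results,
    directory: str | Path,
    zip_archive: bool = False,
    fasta_export: bool = False,
) -> dict[str, Path]:
    """Write the six run files (plus manifest) and return the path manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, text: str) -> None:
        path = directory / name
        try:
            path.write_text(text)
        except OSError as exc:
            raise OSError(f"failed writing output file {name}: {exc}") from exc
        paths[name] = path

    emit("probe_run1_summary", _summary_text(run_results.summary_run1))
    emit("probe_run2_summary", _summary_text(run_results.summary_run2))
    emit("probe_file1", _probe_rows(run_results.probes_run1))
    emit("probe_file2", _probe_rows(run_results.probes_run2))
    import io

    buf = io.StringIO()
    write_clstr(run_results.clusters, buf)
    emit("core_cluster.txt", buf.getvalue())
    nr_lines = [_probe_rows(run_results.nonredundant_probes).rstrip("\n")]
    header, *rows = nr_lines[0].split("\n")
    header += "\tall_cluster_ids"
    out_rows = []
    for p, row in zip(run_results.nonredundant_probes, rows):
        ids = ",".join(str(c) for c in (p.cluster_id, *p.extra_cluster_ids))
        out_rows.append(row + "\t" + ids)
    emit("probe_non_redundant.txt", "\n".join([header, *out_rows]) + "\n")

    manifest_lines = [f"{k}: {v}\n" for k, v in sorted(run_results.manifest.items())]
    emit("run_manifest.txt", "".join(manifest_lines))

    if fasta_export:
        write_probe_fasta(run_results.probes_run2, directory / "probe_file2.fasta")
        paths["probe_file2.fasta"] = directory / "probe_file2.fasta"

    if zip_archive:
        zip_path = directory.with_suffix(".zip")
        with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
            for name in OUTPUT_FILES:
                zf.write(paths[name], arcname=name)
        paths["zip"] = zip_path
    return paths
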