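"""End-to-end run orchestration: ingest -> networks -> nulls -> report.

A run reads two group uptake tables, executes the differential network
analysis under a :class:`~petnet.config.RunConfig`, and writes a complete,
reproducible artifact set: the per-node report TSV, each group's edge list and
correlation matrix, and a JSON manifest recording the configuration, seeds and
a checksum of every output file.  Two runs with equal manifests produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from . import __version__
from .config import RunConfig
from .differential import run_differential_analysis, write_report
from .ingest import normalize_global_mean, read_uptake_table
from .network import correlation_matrix, threshold_network, write_correlation_matrix, write_edge_list

logger = logging.getLogger("petnet")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    group_a_file: str | Path,
    group_b_file: str | Path,
    group_a_name: str = "A",
    group_b_name: str = "B",
) -> Path:
    """Run the full analysis on two uptake tables and write all artifacts.

    Returns the output directory.  Raises with a diagnostic naming the
    failing stage on any validation error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "ingest"
    try:
        groups = []
        for path, name in ((group_a_file, group_a_name), (group_b_file, group_b_name)):
            m = read_uptake_table(path, group=name, missing_policy=config.missing_policy)
            groups.append(m)
        if groups[0].voi_labels != groups[1].voi_labels:
            only_a = set(groups[0].voi_labels) - set(groups[1].voi_labels)
            only_b = set(groups[1].voi_labels) - set(groups[0].voi_labels)
            raise ValueError(
                f"VOI label mismatch between groups: only in {group_a_name}: "
                f"{sorted(only_a)}; only in {group_b_name}: {sorted(only_b)}"
            )

        stage = "network"
        written: list[Path] = []
        for m in groups:
            g = normalize_global_mean(m) if config.normalize else m
            corr = correlation_matrix(g, zero_variance_policy=config.zero_variance_policy)
            net = threshold_network(corr, g.voi_labels, tau=config.tau, group=g.group)
            edge_path = out / f"edges_{m.group}.tsv"
            corr_path = out / f"correlation_{m.group}.tsv"
            write_edge_list(net, edge_path)
            write_correlation_matrix(net, corr_path)
            written += [edge_path, corr_path]
            logger.info("group %s: %d nodes, %d edges at tau=%g", m.group, net.n_nodes, net.n_edges, config.tau)

        stage = "differential_analysis"
        result = run_differential_analysis(groups[0], groups[1], config)
        report_path = out / "report.tsv"
        write_report(result, report_path, precision=config.precision)
        written.append(report_path)

        stage = "manifest"
        manifest = {
            "petnet_version": __version__,
            "config": config.to_dict(),
            "config_fingerprint": config.fingerprint(),
            "inputs": {group_a_name: str(group_a_file), group_b_name: str(group_b_file)},
            "network_stat": result.network_stat,
            "network_p": result.network_p,
            "mean_degree": {group_a_name: result.mean_degree_A, group_b_name: result.mean_degree_B},
            "outputs": {p.name: _sha256(p) for p in written},
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    logger.info("run complete: %s", out)
    return out
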