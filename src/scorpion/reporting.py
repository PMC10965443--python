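"""Human-readable run and comparison summaries with provenance.

Reports are pure functions of their input artifacts: same artifacts, same
bytes.  Numbers are formatted at 6 significant digits; input files are
referenced by SHA-256 checksum so every figure in a report can be traced
back to the artifact that produced it.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Network
from .population import ComparisonResult

__all__ = ["render_report", "file_checksum"]


def file_checksum(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _fmt(x) -> str:
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, (float, np.floating)):
        return f"{x:.6g}"
    return str(x)


def _network_section(net: Network, top_k: int) -> list[tuple[str, str]]:
    rows = [
        ("n_tfs", _fmt(len(net.tf_ids))),
        ("n_genes", _fmt(len(net.gene_ids))),
    ]
    for key in sorted(net.metadata):
        rows.append((f"param.{key}", _fmt(net.metadata[key])))
    frame = net.to_frame()
    flat = frame.stack()
    strongest = flat.abs().sort_values(ascending=False, kind="stable").head(top_k)
    for (tf, gene) in strongest.index:
        rows.append((f"top_edge.{tf}->{gene}", _fmt(flat.loc[(tf, gene)])))
    return rows


def _comparison_section(cmp: ComparisonResult) -> list[tuple[str, str]]:
    rows = [
        ("tf", cmp.tf),
        ("n_genes", _fmt(len(cmp.genes))),
        ("mean_delta", _fmt(cmp.mean_delta)),
        ("t_stat", _fmt(cmp.t_stat)),
        ("p_value", _fmt(cmp.p_value)),
        ("ci_low", _fmt(cmp.ci_low)),
        ("ci_high", _fmt(cmp.ci_high)),
        ("spearman_rho", _fmt(cmp.spearman_rho)),
    ]
    # outliers listed by |delta| descending
    delta = pd.Series(cmp.paired_deltas, index=cmp.genes)
    outliers = delta.loc[list(cmp.outliers_up) + list(cmp.outliers_down)]
    outliers = outliers.iloc[
        np.argsort(-outliers.abs().to_numpy(), kind="stable")
    ]
    for gene, value in outliers.items():
        direction = "up" if gene in cmp.outliers_up else "down"
        rows.append((f"outlier.{direction}.{gene}", _fmt(value)))
    return rows


def render_report(artifacts: dict, format: str = "markdown") -> str:
    """Render a deterministic report over build/comparison artifacts.

    ``artifacts`` may contain any of: ``network`` (:class:`Network`),
    ``comparison`` (:class:`ComparisonResult`), ``tables`` (dict of name
    -> DataFrame summarized by shape and column means), ``inputs`` (dict
    of label -> file path, reported with SHA-256 checksums), ``top_k``
    (int, default 10).  Unknown or missing artifacts raise an error
    naming them.
    """
    if format not in ("markdown", "tsv"):
        raise ValueError(f"format must be 'markdown' or 'tsv', got {format!r}")
    known = {"network", "comparison", "tables", "inputs", "top_k"}
    unknown = set(artifacts) - known
    if unknown:
        raise ValueError(f"unknown artifact(s): {', '.join(sorted(unknown))}")
    if not set(artifacts) & {"network", "comparison", "tables"}:
        raise ValueError(
            "missing artifacts: need at least one of network, comparison, tables"
        )
    top_k = int(artifacts.get("top_k", 10))

    sections: list[tuple[str, list[tuple[str, str]]]] = []
    if "inputs" in artifacts:
        rows = []
        for label in sorted(artifacts["inputs"]):
            path = artifacts["inputs"][label]
            if not Path(path).exists():
                raise ValueError(f"missing artifact file: {path}")
            rows.append((f"sha256.{label}", file_checksum(path)))
        sections.append(("inputs", rows))
    if "network" in artifacts:
        sections.append(("network", _network_section(artifacts["network"], top_k)))
    if "comparison" in artifacts:
        sections.append(("comparison", _comparison_section(artifacts["comparison"])))
    if "tables" in artifacts:
        rows = []
        for name in sorted(artifacts["tables"]):
            table = artifacts["tables"][name]
            rows.append((f"{name}.shape", f"{table.shape[0]}x{table.shape[1]}"))
            for col in table.columns:
                if pd.api.types.is_numeric_dtype(table[col]):
                    rows.append((f"{name}.mean.{col}", _fmt(table[col].mean())))
        sections.append(("tables", rows))

    if format == "tsv":
        lines = ["section\tkey\tvalue"]
        for title, rows in sections:
            for key, value in rows:
                lines.append(f"{title}\t{key}\t{value}")
        return "\n".join(lines) + "\n"

    lines = []
    for title, rows in sections:
        lines.append(f"## {title}")
        lines.append("")
        for key, value in rows:
            lines.append(f"- {key}: {value}")
        lines.append("")
    return "\n".join(lines)
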