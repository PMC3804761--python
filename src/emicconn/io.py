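"""File I/O, cohort manifests, run configuration, and the pipeline driver.

All tabular output is TSV (CSV accepted on input); numbers are written with
17 significant digits so that a write -> read round trip is exact.  Region
numbering in reports is 1-based (atlas convention); internal indices are
0-based.  Every pipeline run writes its resolved configuration next to its
outputs and stamps each report with the configuration hash, so identical
configurations produce byte-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassificationReport, accuracy_sweep
from .connectivity import (
    ConnectivityMatrix,
    EdgeIndex,
    FeatureTable,
    build_connectivity,
    cohort_features,
)
from .consensus import ConsensusNetwork, consensus_from_report
from .errors import ManifestError
from .networks import network_of
from .preprocess import MotionParameters, RegionalTimeSeries, preprocess_pipeline
from .ranking import RankedEdges, rank_edges

logger = logging.getLogger(__name__)

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "read_motion",
    "write_motion",
    "read_manifest",
    "write_manifest",
    "write_matrix",
    "read_matrix",
    "write_ranking",
    "write_consensus",
    "RunConfig",
    "run_pipeline",
]

_FLOAT_FMT = "%.17g"


def _sep_for(path: Path, text: str) -> str:
    first = text.splitlines()[0] if text else ""
    if "\t" in first:
        return "\t"
    if "," in first:
        return ","
    return "\t"


def read_timeseries(path, tr_seconds: float = 2.0) -> RegionalTimeSeries:
    """Read a regions x timepoints table (first column = region label)."""
    path = Path(path)
    text = path.read_text()
    sep = _sep_for(path, text)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    except Exception as exc:  # ragged rows etc.
        raise ManifestError(f"{path}: cannot parse: {exc}") from exc
    labels = [str(l) for l in df.index]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ManifestError(f"{path}: duplicate region labels {dupes}")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    nan_pos = np.argwhere(np.isnan(values))
    if nan_pos.size:
        r, c = nan_pos[0]
        raise ManifestError(
            f"{path}: non-numeric or missing value at region {labels[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return RegionalTimeSeries(values, tuple(labels), tr_seconds)


def write_timeseries(path, series: RegionalTimeSeries) -> None:
    path = Path(path)
    header = "region\t" + "\t".join(
        f"t{i}" for i in range(series.n_timepoints)
    )
    lines = [header]
    for label, row in zip(series.region_labels, series.data):
        lines.append(label + "\t" + "\t".join(_FLOAT_FMT % v for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_motion(path) -> MotionParameters:
    """Read a 6-column (timepoints x 6) or 6-row motion table, no header."""
    arr = np.loadtxt(path, dtype=float, ndmin=2)
    if arr.shape[1] == 6:
        arr = arr.T
    if arr.shape[0] != 6:
        raise ManifestError(f"{path}: expected 6 motion parameters, got {arr.shape}")
    return MotionParameters(arr)


def write_motion(path, motion: MotionParameters) -> None:
    np.savetxt(path, motion.data.T, fmt=_FLOAT_FMT, delimiter="\t")


def read_manifest(path) -> pd.DataFrame:
    """Cohort manifest: TSV/CSV with subject_id, path, label, [motion_path]."""
    path = Path(path)
    sep = _sep_for(path, path.read_text())
    df = pd.read_csv(path, sep=sep, dtype={"subject_id": str})
    required = {"subject_id", "path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {sorted(missing)}")
    if not set(df["label"].astype(int)) <= {-1, 1}:
        raise ManifestError(f"{path}: labels must be +1 or -1")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ManifestError(f"{path}: duplicate subject ids {dupes}")
    return df


def write_manifest(path, rows) -> None:
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)


def write_matrix(path, matrix: ConnectivityMatrix) -> None:
    """Square TSV with region labels on both axes."""
    df = pd.DataFrame(matrix.values, index=matrix.region_labels,
                      columns=matrix.region_labels)
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index_label="region")


def read_matrix(path, measure: str) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ConnectivityMatrix(df.to_numpy(), measure, tuple(df.index))


def write_ranking(path, ranked: RankedEdges, edge_index: EdgeIndex,
                  region_labels=None) -> None:
    """TSV: rank, 1-based region numbers (and labels), tau, power, direction."""
    pairs = edge_index.pairs()
    rows = []
    for e in ranked.order:
        i, j = pairs[e]
        row = {"rank": int(ranked.rank[e]), "region_i": i + 1, "region_j": j + 1}
        if region_labels:
            row["label_i"] = region_labels[i]
            row["label_j"] = region_labels[j]
        row.update(
            tau=_FLOAT_FMT % ranked.tau[e], power=_FLOAT_FMT % ranked.power[e],
            direction=ranked.directions[e].value,
        )
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_consensus(path_edges, path_weights, network: ConsensusNetwork,
                    edge_index: EdgeIndex, region_labels=None) -> None:
    """Consensus edge table plus region-weight table (1-based regions)."""
    pairs = edge_index.pairs()
    rows = []
    for e in network.edges:
        i, j = pairs[e.edge]
        row = {"region_i": i + 1, "region_j": j + 1}
        if region_labels:
            row["label_i"] = region_labels[i]
            row["label_j"] = region_labels[j]
            row["network_i"] = network_of(region_labels[i])
            row["network_j"] = network_of(region_labels[j])
        row.update(
            mean_power=_FLOAT_FMT % e.mean_power,
            normalized_strength=_FLOAT_FMT % e.normalized_strength,
            direction=e.direction.value,
        )
        rows.append(row)
    pd.DataFrame(
        rows, columns=rows[0].keys() if rows else
        ["region_i", "region_j", "mean_power", "normalized_strength", "direction"],
    ).to_csv(path_edges, sep="\t", index=False)
    wrows = [
        {
            "region": r + 1,
            **({"label": region_labels[r],
                "network": network_of(region_labels[r])} if region_labels else {}),
            "weight": w,
        }
        for r, w in sorted(network.region_weights.items())
    ]
    pd.DataFrame(wrows).to_csv(path_weights, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration and pipeline driver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one pipeline run (serializable round-trip).

    ``discard_volumes`` defaults to 0 because synthetic cohorts emit the
    retained volumes only; raw scanner sessions conventionally discard 5.
    """

    manifest: str
    measure: str = "emic"
    k: int = 200
    sweep: tuple[int, ...] | None = None
    discard_volumes: int = 0
    detrend: bool = True
    band: tuple[float, float] | None = (0.01, 0.08)
    tr_seconds: float = 2.0
    standardize: bool = True
    svm_c: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep"] = list(self.sweep) if self.sweep is not None else None
        d["band"] = list(self.band) if self.band is not None else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("sweep") is not None:
            d["sweep"] = tuple(int(k) for k in d["sweep"])
        if d.get("band") is not None:
            d["band"] = tuple(float(b) for b in d["band"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        return cls.from_dict(data)

    def write(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_cohort(config: RunConfig):
    manifest_path = Path(config.manifest)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    subjects, motions = [], []
    for _, row in df.iterrows():
        try:
            series = read_timeseries(base / row["path"], config.tr_seconds)
        except Exception as exc:
            raise ManifestError(
                f"stage=load subject={row['subject_id']}: {exc}"
            ) from exc
        motion = None
        if "motion_path" in df.columns and isinstance(row.get("motion_path"), str):
            motion = read_motion(base / row["motion_path"])
        subjects.append(series)
        motions.append(motion)
    labels = df["label"].astype(int).to_numpy()
    return df["subject_id"].tolist(), subjects, motions, labels


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """simulate/load -> preprocess -> connect -> rank -> classify -> consensus.

    Writes all artifacts under ``out_dir`` and returns the report dict.
    Reruns with an identical configuration are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    logger.info("emicconn %s, config hash %s, seed %d", __version__,
                config.config_hash, config.seed)
    config.write(out_dir / "config.yaml")

    ids, subjects, motions, labels = _load_cohort(config)
    processed = []
    for sid, series, motion in zip(ids, subjects, motions):
        try:
            processed.append(preprocess_pipeline(
                series, motion, discard=config.discard_volumes,
                detrend=config.detrend, band=config.band,
            ))
        except Exception as exc:
            raise ManifestError(f"stage=preprocess subject={sid}: {exc}") from exc

    table = cohort_features(processed, labels, config.measure, subject_ids=ids)
    edge_index = table.edge_index
    region_labels = table.region_labels

    matdir = out_dir / "connectivity"
    matdir.mkdir(exist_ok=True)
    for sid, series in zip(ids, processed):
        write_matrix(matdir / f"{sid}_{config.measure}.tsv",
                     build_connectivity(series, config.measure))

    ranked = rank_edges(table)
    write_ranking(out_dir / "ranking.tsv", ranked, edge_index, region_labels)

    ks = config.sweep if config.sweep is not None else (config.k,)
    reports = accuracy_sweep(table, ks, C=config.svm_c,
                             standardize=config.standardize)
    report_k = reports[config.k if config.sweep is None else ks[0]]

    network = consensus_from_report(report_k, edge_index)
    write_consensus(out_dir / "consensus_edges.tsv",
                    out_dir / "region_weights.tsv", network, edge_index,
                    region_labels)

    bundle = {
        "version": __version__,
        "config_hash": config.config_hash,
        "measure": config.measure,
        "n_subjects": int(table.n_subjects),
        "n_edges": int(table.n_edges),
        "results": {str(k): {"gr": r.gr, "ss": r.ss, "sc": r.sc}
                    for k, r in sorted(reports.items())},
        "consensus": {
            "n_edges": len(network.edges),
            "directions": {
                d: sum(1 for e in network.edges if e.direction.value == d)
                for d in ("decreased_in_patients", "increased_in_patients", "tied")
            },
        },
        "folds": report_k.to_dict()["folds"],
    }
    (out_dir / "report.json").write_text(
        json.dumps(bundle, indent=2, sort_keys=True) + "\n"
    )
    return bundle
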