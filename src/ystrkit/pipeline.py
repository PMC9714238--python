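"""End-to-end workflow: forensic stats -> distances -> MDS/NJ -> network.

``run_all`` executes the full analysis sequence on a genotype table (or
in-memory samples) and writes diff-friendly text artifacts plus a JSON
manifest with the seed, parameter echo, and sha256 of every file.
Given the same inputs and seed the artifact bytes are identical across
runs (no timestamps anywhere).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as yio
from .amova import metric_by_name, pairwise_matrix
from .markers import BUILTIN_PANELS, PopulationSample
from .network import export_network, mj_network
from .ordination import classical_mds
from .stats import allele_frequencies, resolution_table
from .tree import neighbor_joining, write_newick

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)

try:
    _VERSION = _pkg_version("ystrkit")
except PackageNotFoundError:  # running from a source tree
    _VERSION = "0.1.0"


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full pipeline run."""

    input: str | Path | None
    outdir: str | Path
    panels: tuple[str, ...] = ("mh9", "swgdam11", "ppy12", "yfiler17")
    metric: str = "rst"
    permutations: int = 0
    seed: int = 0
    epsilon: float = 0.0
    log_level: str = "INFO"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(cfg: RunConfig) -> str:
    return f"ystrkit {_VERSION} seed={cfg.seed}"


def run_all(
    cfg: RunConfig, samples: Sequence[PopulationSample] | None = None
) -> dict:
    """Run the full workflow; returns the manifest (also written to disk)."""
    logging.basicConfig(level=cfg.log_level)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if samples is None:
        if cfg.input is None:
            raise ValueError("either an input table or samples must be given")
        samples = yio.load_genotype_table(cfg.input)
    samples = sorted(samples, key=lambda s: s.label)
    panels = [BUILTIN_PANELS[p] for p in cfg.panels]

    manifest: dict = {
        "tool": "ystrkit",
        "version": _VERSION,
        "seed": cfg.seed,
        "parameters": {
            "panels": list(cfg.panels),
            "metric": cfg.metric,
            "permutations": cfg.permutations,
            "epsilon": cfg.epsilon,
        },
        "populations": {s.label: s.n for s in samples},
        "artifacts": [],
        "failures": [],
    }

    def emit(name: str, writer) -> None:
        path = outdir / name
        try:
            writer(path)
        except Exception as exc:  # noqa: BLE001 - stage isolation by contract
            log.error("stage %s failed: %s", name, exc)
            manifest["failures"].append({"artifact": name, "error": str(exc)})
            return
        manifest["artifacts"].append({"file": name, "sha256": _sha256(path)})

    def write_summary(path: Path) -> None:
        frames = [resolution_table(s, panels) for s in samples]
        with open(path, "w") as fh:
            fh.write(f"# {_provenance(cfg)}\n")
            pd.concat(frames, ignore_index=True).to_csv(fh, sep="\t", index=False)

    def write_frequencies(path: Path) -> None:
        rows = []
        for s in samples:
            for locus in s.panel.locus_names:
                ft = allele_frequencies(s, locus)
                for key in sorted(ft.counts, key=str):
                    rows.append(
                        {
                            "population": s.label,
                            "locus": locus,
                            "allele": (
                                "-".join(f"{x:g}" for x in key)
                                if isinstance(key, tuple)
                                else f"{key:g}"
                            ),
                            "count": ft.counts[key],
                            "frequency": ft.frequency(key),
                        }
                    )
        with open(path, "w") as fh:
            fh.write(f"# {_provenance(cfg)}\n")
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)

    dms = {}

    def make_dist(kind: str):
        dm = pairwise_matrix(
            samples,
            metric_by_name(kind),
            n_perm=cfg.permutations,
            seed=cfg.seed,
        )
        dms[kind] = dm
        return dm

    def write_dist(kind: str):
        def _w(path: Path) -> None:
            dm = make_dist(kind)
            yio.write_distance_matrix(
                dm.labels, dm.values, path, pvalues=dm.pvalues,
                header_comment=f"{_provenance(cfg)} metric={kind}",
            )
        return _w

    emit("summary.tsv", write_summary)
    emit("frequencies.tsv", write_frequencies)
    emit("dist_rst.tsv", write_dist("rst"))
    emit("dist_fst.tsv", write_dist("fst"))

    def write_mds(path: Path) -> None:
        dm = dms["rst"]
        emb = classical_mds(dm.labels, dm.values, dims=2)
        df = pd.DataFrame(
            emb.coordinates, index=list(emb.labels), columns=["dim1", "dim2"]
        )
        with open(path, "w") as fh:
            fh.write(f"# {_provenance(cfg)} strain={emb.strain:.6g}\n")
            df.to_csv(fh, sep="\t", index_label="population")

    def write_tree(path: Path) -> None:
        dm = dms["fst"]
        t = neighbor_joining(dm.labels, dm.values)
        path.write_text(write_newick(t) + "\n")

    def write_net(path: Path) -> None:
        net = mj_network(samples, epsilon=cfg.epsilon)
        path.write_text(export_network(net))

    emit("mds.tsv", write_mds)
    emit("tree.nwk", write_tree)
    emit("network.gml", write_net)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
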