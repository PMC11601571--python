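"""End-to-end pipeline: scores -> QTVs -> genome scan -> prioritization.

A single YAML/dict config drives the run; every stage writes TSV outputs
into the output directory and is recorded in a JSON manifest with the
parameters, seeds, and input checksums needed to reproduce it.  Stages
are individually resumable: with ``resume=True`` a stage whose outputs
already exist is skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import genomescan as gs
from . import prioritize as pz
from . import qtv as qv
from . import scores as sc

logger = logging.getLogger(__name__)

STAGES = ("scores", "qtv", "scan", "prioritize", "variants")

DEFAULTS = {
    "window": [5, 50],
    "alphas": [0.15, 0.20],
    "n_perm": 1000,
    "n_svm": 100,
    "seed": 0,
    "kinship": "none",  # none / overall / loco
    "traits": ["mean_cds"],
}


class StageError(RuntimeError):
    def __init__(self, stage, exc):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _check_paths(config):
    missing = []
    for key in ("scores", "probs", "variants"):
        p = config.get(key)
        if p and not Path(p).exists():
            missing.append(str(p))
    for net in config.get("networks", []):
        if not Path(net["path"]).exists():
            missing.append(str(net["path"]))
    for key in ("positives", "negative_pool", "candidates"):
        p = config.get(key)
        if p and not Path(p).exists():
            missing.append(str(p))
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")


def _read_gene_list(path):
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def run_pipeline(config: dict, outdir, resume: bool = False) -> dict:
    """Run all configured stages; return the manifest dict.

    Referenced input paths are checked up front so a missing file fails
    before any compute.  A stage failure raises StageError naming the
    stage; outputs of completed stages are preserved.
    """
    cfg = {**DEFAULTS, **config}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_paths(cfg)
    manifest = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items() if k != "networks"}
        | {"networks": [n["path"] for n in cfg.get("networks", [])]},
        "inputs": {},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for key in ("scores", "probs", "variants", "positives", "negative_pool", "candidates"):
        if cfg.get(key):
            manifest["inputs"][key] = _sha256(cfg[key])
    for net in cfg.get("networks", []):
        manifest["inputs"][f"network:{net.get('tissue', net['path'])}"] = _sha256(net["path"])

    def _done(stage, outputs):
        manifest["stages"][stage] = {"outputs": [str(p) for p in outputs]}
        _write_manifest(manifest, outdir)

    def _skip(stage, outputs):
        paths = [outdir / o for o in outputs]
        if resume and all(p.exists() for p in paths):
            logger.info("stage %s: outputs exist, skipping (resume)", stage)
            manifest["stages"][stage] = {"outputs": [str(p) for p in paths], "resumed": True}
            return True
        return False

    window = tuple(cfg["window"])
    table = qtv_df = summary = None

    # -- stage: scores -----------------------------------------------------
    if cfg.get("scores"):
        outs = ["preprocessed_scores.tsv", "excluded.tsv"]
        try:
            table = sc.apply_endpoint_rules(sc.read_scores(cfg["scores"], window=window))
            if not _skip("scores", outs):
                sc.write_scores(table, outdir / outs[0])
                pd.DataFrame(table.excluded, columns=["mouse_id", "reason"]).to_csv(
                    outdir / outs[1], sep="\t", index=False
                )
                _done("scores", [outdir / o for o in outs])
        except StageError:
            raise
        except Exception as exc:
            raise StageError("scores", exc) from exc

    # -- stage: qtv --------------------------------------------------------
    if table is not None:
        outs = ["qtv.tsv", "strain_summary.tsv"]
        try:
            qtv_df = qv.derive_qtv(table)
            summary = qv.summarize_strain(qtv_df)
            if not _skip("qtv", outs):
                qtv_df.to_csv(outdir / outs[0], sep="\t", index=False)
                summary.to_csv(outdir / outs[1], sep="\t", index=False)
                _done("qtv", [outdir / o for o in outs])
        except StageError:
            raise
        except Exception as exc:
            raise StageError("qtv", exc) from exc

    # -- stage: scan -------------------------------------------------------
    if cfg.get("probs") and summary is not None:
        try:
            probs = gs.GenotypeProbs.read(cfg["probs"])
            kin = None
            if cfg["kinship"] == "overall":
                kin = gs.compute_kinship(probs)
            elif cfg["kinship"] == "loco":
                kin = gs.compute_kinship(probs, loco=True)
            outputs = []
            for trait in cfg["traits"]:
                outs = [f"scan_{trait}.tsv", f"peaks_{trait}.tsv"]
                if _skip(f"scan:{trait}", outs):
                    continue
                if trait == "cds":  # mouse-level, batch-corrected
                    vals = gs.preprocess_phenotype(
                        qtv_df["cds"].to_numpy(), qtv_df["cohort"].to_numpy()
                    )
                    phen = gs.PhenotypeVector(
                        vals, qtv_df["strain"].to_numpy(dtype=object), unit="mouse"
                    )
                else:  # per-strain summary column
                    col = qv.strain_phenotype(summary, trait)
                    phen = gs.PhenotypeVector(
                        gs.rank_z(col.to_numpy()),
                        col.index.to_numpy(dtype=object),
                        unit="strain",
                    )
                res = gs.scan(probs, phen, kinship=kin)
                res.thresholds = gs.permutation_thresholds(
                    probs,
                    phen,
                    n_perm=cfg["n_perm"],
                    alphas=cfg["alphas"],
                    seed=cfg["seed"],
                    kinship=kin,
                )
                res = gs.find_peaks(probs, res, phen, kinship=kin)
                res.lod.to_csv(outdir / outs[0], sep="\t", index=False)
                peaks = res.peaks.copy()
                peaks.insert(0, "trait", trait)
                for a, t in res.thresholds.items():
                    peaks[f"thr_{a:g}"] = t
                peaks.to_csv(outdir / outs[1], sep="\t", index=False)
                _done(f"scan:{trait}", [outdir / o for o in outs])
                outputs += outs
        except StageError:
            raise
        except Exception as exc:
            raise StageError("scan", exc) from exc

    # -- stage: prioritize -------------------------------------------------
    if cfg.get("networks") and cfg.get("positives"):
        try:
            positives = _read_gene_list(cfg["positives"])
            pool = _read_gene_list(cfg["negative_pool"]) if cfg.get("negative_pool") else []
            cands = _read_gene_list(cfg["candidates"]) if cfg.get("candidates") else []
            for net_cfg in cfg["networks"]:
                tissue = net_cfg.get("tissue", Path(net_cfg["path"]).stem)
                outs = [f"prioritization_{tissue}.tsv"]
                if _skip(f"prioritize:{tissue}", outs):
                    continue
                net = pz.GeneNetwork.read(net_cfg["path"], tissue=tissue)
                if not pool:
                    used = set(positives) | set(cands)
                    pool = sorted(net.genes - used)
                scores = pz.prioritize_qtl(
                    net, positives, pool, cands, n_svm=cfg["n_svm"], seed=cfg["seed"]
                )
                scores.to_csv(outdir / outs[0], sep="\t", index=False)
                _done(f"prioritize:{tissue}", [outdir / o for o in outs])
        except StageError:
            raise
        except Exception as exc:
            raise StageError("prioritize", exc) from exc

    # -- stage: variants ---------------------------------------------------
    if cfg.get("variants") and cfg.get("nssnp"):
        try:
            outs = ["nssnp.tsv"]
            if not _skip("variants", outs):
                vt = pd.read_csv(cfg["variants"], sep=None, engine="python")
                spec = cfg["nssnp"]
                filtered = pz.nssnp_segregating(
                    vt,
                    (spec["chrom"], float(spec["lo_Mb"]), float(spec["hi_Mb"])),
                    spec["founder_a"],
                    spec["founder_b"],
                    genes=spec.get("genes"),
                )
                filtered.to_csv(outdir / outs[0], sep="\t", index=False)
                _done("variants", [outdir / o for o in outs])
        except StageError:
            raise
        except Exception as exc:
            raise StageError("variants", exc) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest, outdir):
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
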