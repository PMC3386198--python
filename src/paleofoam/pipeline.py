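"""End-to-end pipeline: run the analysis stages from one YAML config.

Stages (all optional, run in dependency order):

    simulate -> consensus -> defects -> dupsets -> k2p -> date_pair
             -> date_set -> codivergence

Every run writes a manifest recording the tool version, a hash of the
config, all seeds, digests of the input files and the outputs of each
stage, so that a rerun with the same manifest reproduces the outputs
byte for byte.  Numeric results go to structured JSON/TSV files, never
only to the log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .consensus import annotate_defects, build_consensus, identify_duplicate_sets
from .cophylogeny import (
    codivergence_test,
    extract_branch_pairs,
    map_congruent_branches,
    midpoint_root,
    parse_newick,
    write_newick,
)
from .dating import RatePrior, date_duplication_set, date_pair
from .distances import k2p_from_pair
from .records import read_alignment, read_fasta, write_fasta
from .simulate import SimulationConfig, simulate_endogenization

log = logging.getLogger("paleofoam")

STAGE_ORDER = [
    "simulate", "consensus", "defects", "dupsets",
    "k2p", "date_pair", "date_set", "codivergence",
]


class ConfigError(ValueError):
    """Invalid pipeline configuration (reported before any stage runs)."""


class StageError(RuntimeError):
    """A stage failed; downstream stages were skipped."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a YAML mapping of stage blocks")
    return cfg


def validate_config(cfg: dict[str, Any]) -> None:
    """Fail fast: check stage names and that referenced inputs exist."""
    unknown = set(cfg) - set(STAGE_ORDER) - {"output_dir", "seed"}
    if unknown:
        raise ConfigError(f"unknown config blocks: {sorted(unknown)}")
    if not any(s in cfg for s in STAGE_ORDER):
        raise ConfigError("config requests no stages")
    for stage, block in cfg.items():
        if stage not in STAGE_ORDER or not isinstance(block, dict):
            continue
        for key in ("fasta", "alignment", "host_tree", "virus_tree", "tip_map",
                    "coords"):
            if key in block and not Path(block[key]).exists():
                raise ConfigError(
                    f"stage {stage!r}: input {key}={block[key]!r} does not exist"
                )


def run_pipeline(
    cfg: dict[str, Any] | str | Path, output_dir: str | Path | None = None
) -> dict[str, Any]:
    """Execute the configured stages and return the run manifest."""
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    validate_config(cfg)
    out = Path(output_dir or cfg.get("output_dir", "paleofoam_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    manifest: dict[str, Any] = {
        "tool": "paleofoam",
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "inputs": {},
    }

    ctx: dict[str, Any] = {}
    for stage in STAGE_ORDER:
        if stage not in cfg:
            continue
        block = dict(cfg[stage] or {})
        log.info("stage %s: starting", stage)
        t0 = time.time()
        try:
            outputs = _STAGES[stage](block, ctx, out, seed, manifest)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out)
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 3),
            "outputs": outputs,
        }
        log.info("stage %s: done (%.2fs)", stage, time.time() - t0)
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict[str, Any], out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _record_input(manifest: dict, path: str | Path) -> None:
    p = Path(path)
    manifest["inputs"][str(p)] = _sha256(p)


def _stage_simulate(block, ctx, out, seed, manifest):
    fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    kwargs = {k: v for k, v in block.items() if k in fields}
    if "host_neutral_rate" in kwargs:
        r = kwargs["host_neutral_rate"]
        kwargs["host_neutral_rate"] = RatePrior(float(r["mean"]), float(r.get("sd", 0.0)))
    kwargs.setdefault("seed", seed)
    sim = simulate_endogenization(SimulationConfig(**kwargs))
    ctx["simulation"] = sim
    aln_path = out / "simulated_elements.fasta"
    write_fasta(sim.element_alignment.records, aln_path)
    frag_path = out / "simulated_contigs.fasta"
    write_fasta(sim.fragments, frag_path)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(sim.truth.to_dict(), indent=2))
    return {"elements": str(aln_path), "contigs": str(frag_path),
            "truth": str(truth_path)}


def _load_alignment(block, ctx, key="alignment"):
    if key in block:
        return read_alignment(block[key])
    sim = ctx.get("simulation")
    if sim is None:
        raise ConfigError(f"no {key!r} given and no simulate stage ran")
    return sim.element_alignment


def _stage_consensus(block, ctx, out, seed, manifest):
    if "alignment" in block:
        _record_input(manifest, block["alignment"])
    aln = _load_alignment(block, ctx)
    res = build_consensus(aln, min_support=float(block.get("min_support", 0.5)))
    path = out / "consensus.fasta"
    write_fasta([res.record], path)
    ctx["consensus"] = res
    return {"consensus": str(path), "columns": int(len(res.record))}


def _stage_defects(block, ctx, out, seed, manifest):
    if "fasta" in block:
        _record_input(manifest, block["fasta"])
        records = read_fasta(block["fasta"])
    else:
        sim = ctx.get("simulation")
        if sim is None:
            raise ConfigError("defects stage needs 'fasta' or a simulate stage")
        records = [c.record for c in sim.contigs]
    span = block.get("orf")
    reports = {}
    for rec in records:
        s, e = (int(span[0]), int(span[1])) if span else (0, len(rec) - len(rec) % 3)
        reports[rec.id] = annotate_defects(rec, s, e).to_dict()
    path = out / "defects.json"
    path.write_text(json.dumps(reports, indent=2))
    return {"defects": str(path)}


def _stage_dupsets(block, ctx, out, seed, manifest):
    sim = ctx.get("simulation")
    if sim is None:
        raise ConfigError("dupsets stage currently requires a simulate stage")
    sets = identify_duplicate_sets(
        sim.contigs,
        flank_window=int(block.get("flank_window", 100)),
        min_flank_identity=float(block.get("min_flank_identity", 0.90)),
    )
    path = out / "duplicate_sets.json"
    path.write_text(json.dumps(sets, indent=2))
    ctx["dupsets"] = sets
    return {"duplicate_sets": str(path), "n_sets": len(sets)}


def _stage_k2p(block, ctx, out, seed, manifest):
    aln = _load_alignment(block, ctx)
    if len(aln) < 2:
        raise ConfigError("k2p stage needs at least 2 aligned sequences")
    est = k2p_from_pair(aln[0], aln[1])
    path = out / "k2p.json"
    path.write_text(json.dumps(est.to_dict(), indent=2))
    ctx["k2p"] = est
    return {"k2p": str(path), "d": est.d}


def _rate_from(block) -> RatePrior:
    return RatePrior(
        mean=float(block.get("rate", 2.2e-9)),
        sd=float(block.get("rate_sd", 0.1e-9)),
    )


def _stage_date_pair(block, ctx, out, seed, manifest):
    d = block.get("d", None)
    est = ctx.get("k2p") if d is None else float(d)
    if est is None:
        raise ConfigError("date_pair needs 'd' or a k2p stage")
    age = date_pair(est, _rate_from(block))
    path = out / "age_pair.json"
    path.write_text(json.dumps(age.to_dict(), indent=2))
    return {"age": str(path), "t_my": age.t_my}


def _stage_date_set(block, ctx, out, seed, manifest):
    aln = _load_alignment(block, ctx)
    age, tree = date_duplication_set(
        aln,
        rate=_rate_from(block),
        n_bootstrap=int(block.get("bootstrap", 1000)),
        seed=int(block.get("seed", seed)),
    )
    path = out / "age_set.json"
    path.write_text(json.dumps(age.to_dict(), indent=2))
    tree_path = out / "clock_tree.nwk"
    tree_path.write_text(write_newick(tree) + "\n")
    return {"age": str(path), "tree": str(tree_path), "t_my": age.t_my}


def _stage_codivergence(block, ctx, out, seed, manifest):
    for key in ("host_tree", "virus_tree", "tip_map"):
        if key not in block:
            raise ConfigError(f"codivergence stage needs {key!r}")
        _record_input(manifest, block[key])
    host = parse_newick(Path(block["host_tree"]).read_text())
    virus = parse_newick(Path(block["virus_tree"]).read_text())
    rooting = block.get("root", "none")
    if rooting == "midpoint":
        virus = midpoint_root(virus)
    tmap = {}
    for line in Path(block["tip_map"]).read_text().splitlines():
        if line.strip() and not line.startswith("#"):
            v, h = line.split("\t")[:2]
            tmap[v.strip()] = h.strip()
    result = map_congruent_branches(host, virus, tmap)
    if not result.congruent:
        raise StageError(
            "host and virus topologies are not congruent; "
            f"host-only clades: {[sorted(c) for c in result.host_only]}"
        )
    pairs = extract_branch_pairs(result, host, virus)
    fit = codivergence_test(
        pairs,
        n_permutations=int(block.get("permutations", 10000)),
        seed=int(block.get("seed", seed)),
    )
    pairs_path = out / "branch_pairs.tsv"
    pairs.to_csv(pairs_path, sep="\t", index=False)
    fit_path = out / "codivergence.json"
    fit_path.write_text(json.dumps(fit.to_dict(), indent=2))
    return {"branch_pairs": str(pairs_path), "fit": str(fit_path),
            "r_squared": fit.r_squared}


_STAGES = {
    "simulate": _stage_simulate,
    "consensus": _stage_consensus,
    "defects": _stage_defects,
    "dupsets": _stage_dupsets,
    "k2p": _stage_k2p,
    "date_pair": _stage_date_pair,
    "date_set": _stage_date_set,
    "codivergence": _stage_codivergence,
}
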