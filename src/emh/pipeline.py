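"""End-to-end pipeline orchestration with a single config and seed.

A run config (YAML/JSON-style dict) enables stages and carries their
parameter blocks; ``run_pipeline`` validates the whole config up front,
executes the enabled stages in dependency order (simulate -> score ->
composition -> expansion -> identity -> gsea -> lda) and writes a manifest
recording parameters, per-stage seeds and SHA-256 hashes of every output.
Per-stage seeds are derived deterministically from the top-level seed and
the stage name, so re-running an identical config reproduces identical
outputs (and hashes) without seed collisions between stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import ValidationError, derive_seed, logger
from . import composition as comp_mod
from . import expansion as exp_mod
from . import identity as id_mod
from . import simulate as sim_mod
from .enrichment import RankedList, preranked_gsea
from .io import (
    normalize,
    read_cell_table,
    read_counts,
    read_gmt,
    write_cell_table,
    write_counts,
    write_gmt,
)
from .lda import lda_frequency
from .signatures import score_all, score_cell_cycle

STAGES = ("simulate", "score", "composition", "expansion", "identity", "gsea", "lda")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    out_dir: Path
    seed: int = 0
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "out_dir" not in raw:
            raise ValidationError("config needs out_dir")
        stages = {k: v for k, v in raw.items() if k in STAGES}
        cfg = cls(out_dir=Path(raw["out_dir"]), seed=int(raw.get("seed", 0)), stages=stages)
        cfg.validate()
        return cfg

    def enabled(self, stage: str) -> bool:
        block = self.stages.get(stage)
        return block is not None and block.get("enabled", True)

    def validate(self) -> None:
        """Check every enabled stage can resolve its inputs before any
        stage runs."""
        problems = []
        have_counts = self.enabled("simulate") or (
            "counts_dir" in self.stages.get("score", {})
        )
        for stage in ("score", "composition", "expansion", "identity", "gsea"):
            if self.enabled(stage) and not have_counts:
                problems.append(f"stage {stage!r} enabled but no counts source "
                                "(enable simulate or give score.counts_dir)")
                break
        if self.enabled("identity"):
            blk = self.stages["identity"]
            if not (blk.get("pole_a") and blk.get("pole_b")):
                problems.append("identity stage needs pole_a and pole_b cluster labels")
        if self.enabled("gsea") and not self.enabled("identity"):
            problems.append("gsea stage needs the identity stage (ranking metric from its DE)")
        if self.enabled("expansion"):
            if "branches" not in self.stages["expansion"]:
                problems.append("expansion stage needs a 'branches' mapping "
                                "(branch -> ordered {stage: [clusters]})")
        if self.enabled("lda"):
            blk = self.stages["lda"]
            if "table" not in blk and "simulate" not in blk:
                problems.append("lda stage needs 'table' (TSV path) or a 'simulate' block")
        if problems:
            raise ValidationError("invalid run config: " + "; ".join(problems))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig | dict) -> dict:
    """Execute all enabled stages; return (and write) the run manifest."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, params: dict, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": derive_seed(config.seed, stage),
            "params": params,
        }
        for p in paths:
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    counts = cells = norm = None
    try:
        if config.enabled("simulate"):
            blk = dict(config.stages["simulate"])
            blk.pop("enabled", None)
            preset = blk.pop("preset", "default_hspc")
            seed = derive_seed(config.seed, "simulate")
            if preset == "default_hspc":
                sim_cfg = sim_mod.default_hspc_config(seed=seed, **blk)
            elif preset == "identity_training":
                sim_cfg = sim_mod.identity_training_config(seed=seed, **blk)
            else:
                raise ValidationError(f"unknown simulate preset {preset!r}")
            ds = sim_mod.simulate_dataset(sim_cfg)
            counts, cells = ds.counts, ds.cells
            paths = list(write_counts(counts, out / "counts").values())
            paths.append(write_cell_table(cells, out / "cells.tsv"))
            truth = out / "truth.json"
            truth.write_text(json.dumps(ds.truth(), indent=2, default=str))
            paths.append(truth)
            record("simulate", {"preset": preset, **blk}, paths)
        elif any(config.enabled(s) for s in STAGES[1:-1]):
            blk = config.stages.get("score", {})
            cdir = Path(blk["counts_dir"])
            counts = read_counts(cdir / "matrix.mtx", cdir / "genes.tsv", cdir / "cells.tsv")
            cells = read_cell_table(blk["cells"])

        if counts is not None:
            norm = normalize(counts)

        if config.enabled("score"):
            blk = config.stages["score"]
            seed = derive_seed(config.seed, "score")
            paths = []
            if blk.get("gmt"):
                scores = score_all(norm, read_gmt(blk["gmt"]), seed=seed)
                scores.to_csv(out / "scores.tsv", sep="\t", index=False)
                paths.append(out / "scores.tsv")
            cc = None
            if blk.get("cc_gmt"):
                cc = read_gmt(blk["cc_gmt"])
            elif config.enabled("simulate"):
                cc = sim_mod.cell_cycle_gene_sets(
                    sim_mod.default_hspc_config(seed=derive_seed(config.seed, "simulate"))
                )
            if cc is not None:
                phases = score_cell_cycle(norm, cc, seed=seed)
                phases.to_csv(out / "phases.tsv", sep="\t", index=False)
                paths.append(out / "phases.tsv")
                cells = cells.drop(columns=["phase"]).merge(
                    phases[["cell_id", "phase"]], on="cell_id", how="left")
            record("score", {k: str(v) for k, v in blk.items()}, paths)

        if config.enabled("composition"):
            blk = config.stages["composition"]
            group_map = blk.get("groups")
            table = comp_mod.cluster_fractions(cells, group_map)
            table.to_csv(out / "composition.tsv", sep="\t", index=False)
            paths = [out / "composition.tsv"]
            if "ratio" in blk:
                ratio = comp_mod.group_ratio(table, blk["ratio"]["numerator"],
                                             blk["ratio"]["denominator"])
                ratio.to_csv(out / "ratios.tsv", sep="\t", index=False)
                paths.append(out / "ratios.tsv")
            cyc = comp_mod.cycling_fractions(cells)
            cyc.to_csv(out / "cycling.tsv", sep="\t", index=False)
            paths.append(out / "cycling.tsv")
            record("composition", {}, paths)

        if config.enabled("expansion"):
            blk = config.stages["expansion"]
            rows = []
            for branch, spec in blk["branches"].items():
                branch_spec = [(stage, set(members)) for stage, members in spec.items()]
                models = exp_mod.build_branch_model(cells, branch_spec, branch)
                for (donor, tissue), model in models.items():
                    res = exp_mod.estimate_expansion(model)
                    frame = res.as_frame()
                    frame.insert(0, "branch", branch)
                    frame.insert(1, "donor_id", donor)
                    frame.insert(2, "tissue", tissue)
                    rows.append(frame)
                    rows.append(pd.DataFrame({
                        "branch": [branch], "donor_id": [donor], "tissue": [tissue],
                        "transition": ["TOTAL"], "amplification": [np.nan],
                        "divisions": [res.total_divisions],
                    }))
            pd.concat(rows, ignore_index=True).to_csv(out / "expansion.tsv", sep="\t", index=False)
            record("expansion", {"branches": list(blk["branches"])}, [out / "expansion.tsv"])

        identity_de = None
        if config.enabled("identity"):
            blk = config.stages["identity"]
            seed = derive_seed(config.seed, "identity")
            pole_a, pole_b = blk["pole_a"], blk["pole_b"]
            cells_a = cells.loc[cells["cluster"] == pole_a, "cell_id"].tolist()
            cells_b = cells.loc[cells["cluster"] == pole_b, "cell_id"].tolist()
            identity_de = id_mod.wilcoxon_de(norm, cells_a, cells_b)
            identity_de.to_csv(out / "identity_de.tsv", sep="\t", index=False)
            sig = id_mod.derive_identity_signature(
                identity_de,
                n_top=blk.get("n_top", 50),
                fdr_cut=blk.get("fdr_cut", 0.05),
                lfc_cut=blk.get("lfc_cut", 0.2),
            )
            write_gmt(sig.to_collection(), out / "identity_signature.gmt")
            res = id_mod.compute_identity_ratio(norm, sig, seed=seed)
            res.per_cell.to_csv(out / "identity.tsv", sep="\t", index=False)
            summary = {
                "median_ratio": res.median_ratio, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "n_cells": res.n_cells,
                "label": id_mod.classify_identity(res),
            }
            (out / "identity_summary.json").write_text(json.dumps(summary, indent=2))
            record("identity", {"pole_a": pole_a, "pole_b": pole_b},
                   [out / "identity_de.tsv", out / "identity_signature.gmt",
                    out / "identity.tsv", out / "identity_summary.json"])

        if config.enabled("gsea"):
            blk = config.stages["gsea"]
            seed = derive_seed(config.seed, "gsea")
            metric = pd.Series(
                -np.log10(np.maximum(identity_de["p"].to_numpy(), 1e-300))
                * np.sign(identity_de["log2_fc"].to_numpy()),
                index=identity_de["gene"],
            )
            ranked = RankedList.from_series(metric)
            if blk.get("gmt"):
                sets = read_gmt(blk["gmt"])
            else:
                sets = id_mod.IdentitySignature.from_collection(
                    read_gmt(out / "identity_signature.gmt")).to_collection()
            res = preranked_gsea(ranked, sets, n_perm=blk.get("n_perm", 1000), seed=seed)
            res.to_csv(out / "gsea.tsv", sep="\t", index=False)
            record("gsea", {"n_perm": blk.get("n_perm", 1000)}, [out / "gsea.tsv"])

        if config.enabled("lda"):
            blk = config.stages["lda"]
            seed = derive_seed(config.seed, "lda")
            if "table" in blk:
                table = pd.read_csv(blk["table"], sep="\t")
            else:
                sb = blk["simulate"]
                table = sim_mod.simulate_lda(sb["true_frequency"], sb["doses"],
                                             sb["n_per_dose"], seed=seed)
            table.to_csv(out / "lda_table.tsv", sep="\t", index=False)
            res = lda_frequency(table, conf_level=blk.get("conf_level", 0.95))
            (out / "lda_result.json").write_text(json.dumps({
                "frequency": res.frequency, "ci_low": res.ci_low, "ci_high": res.ci_high,
                "one_in": res.one_in, "conf_level": res.conf_level, "flags": res.flags,
            }, indent=2))
            record("lda", {}, [out / "lda_table.tsv", out / "lda_result.json"])
    except Exception:
        manifest["failed"] = True
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        logger.exception("pipeline halted; manifest records completed stages")
        raise

    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
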