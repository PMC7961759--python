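"""End-to-end pipeline orchestration.

Stages: simulate -> preprocess -> cluster -> signature -> score ->
methyl-assign -> survival.  Each stage writes its outputs plus a JSON
manifest entry (parameters, seed, input checksums); reruns with the same
config and seed are bit-identical for the deterministic stages.  Stage seeds
are fanned out deterministically from the global seed and the stage name so
stages can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import methyl, score, subtype, surv
from .degsig import SignatureSet, extract_signature, moderated_de
from .preprocess import correct_batch, log_transform, top_variable_genes
from .simcohort import CohortSpec, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

log = logging.getLogger("mprog")

STAGES = ("simulate", "preprocess", "cluster", "signature", "score",
          "methyl-assign", "survival")


@dataclass
class PipelineConfig:
    """Validated pipeline parameters; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "mprog_run"
    # simulate
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    # preprocess
    top_n_genes: int = 2000
    log_pseudocount: float = 1.0
    # cluster
    k_min: int = 2
    k_max: int = 6
    n_resamples: int = 1000
    sample_frac: float = 0.8
    delta_threshold: float = 0.025
    sigclust_sims: int = 100
    # signature
    fdr: float = 0.05
    lfc: float = 2.0
    progressive_subtype: int = 3
    # score
    tau: float = 0.25
    ssgsea_normalize: bool = True
    # methyl
    arm_loss_threshold: float = 0.1
    cimp_sd_threshold: float = 0.2
    cimp_hyper_beta: float = 0.5
    si_threshold: float = 0.5
    # survival
    endpoint: str = "event"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def validate(self) -> None:
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ValueError("need 2 <= k_min <= k_max")
        if not 0 < self.sample_frac <= 1:
            raise ValueError("sample_frac must be in (0, 1]")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")
        spec = self.cohort_spec()
        spec.validate()
        n_samples = sum(spec.n_per_subtype)
        if self.k_max >= n_samples:
            raise ValueError(
                f"k_max={self.k_max} must be below the sample count "
                f"{n_samples}")

    def cohort_spec(self) -> CohortSpec:
        overrides = dict(self.cohort)
        for key in ("n_per_subtype", "arm_means"):
            if key in overrides and isinstance(overrides[key], list):
                overrides[key] = tuple(
                    tuple(v) if isinstance(v, list) else v
                    for v in overrides[key]) if key == "arm_means" \
                    else tuple(overrides[key])
        overrides.setdefault("seed", stage_seed(self.seed, "simulate"))
        return CohortSpec(**overrides)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on a simulated cohort and write outputs + manifest.

    Returns the run directory.  A stage failure aborts with the failing
    stage named; outputs of completed stages are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "seed": config.seed,
                      "stages": {}, "version": __import__("mprog").__version__}
    manifest_path = outdir / "manifest.json"

    state: dict = {}
    for stage in STAGES:
        t0 = _time.time()
        try:
            outputs = _STAGE_FUNCS[stage](config, outdir, state)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            manifest_path.write_text(json.dumps(manifest, indent=2,
                                                sort_keys=True))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        entry = {
            "status": "complete",
            "seconds": round(_time.time() - t0, 3),
            "seed": stage_seed(config.seed, stage),
            "outputs": {name: _checksum(outdir / name) for name in outputs},
        }
        param_blob = json.dumps(manifest["config"], sort_keys=True) + stage
        entry["parameter_hash"] = hashlib.sha256(
            param_blob.encode()).hexdigest()[:16]
        manifest["stages"][stage] = entry
        log.info("stage=%s wall=%.2fs seed=%d hash=%s", stage,
                 entry["seconds"], entry["seed"], entry["parameter_hash"])

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


# --- stage implementations --------------------------------------------------

def _stage_simulate(cfg, outdir, state):
    cohort = simulate_cohort(cfg.cohort_spec())
    state["cohort"] = cohort
    mio.write_gct(cohort.expression, outdir / "expression.gct")
    mio.write_matrix_tsv(cohort.expression, outdir / "expression.tsv")
    cohort.annotations.to_csv(outdir / "annotations.csv")
    cohort.survival.to_csv(outdir / "survival.csv")
    cohort.methylation.round(8).to_csv(outdir / "beta.tsv", sep="\t")
    cohort.cpg_annotations.to_csv(outdir / "cpg_annotations.csv")
    cohort.arm_cn.to_csv(outdir / "arm_cn.tsv", sep="\t")
    (outdir / "truth.json").write_text(
        json.dumps(cohort.truth, indent=2, sort_keys=True))
    return ["expression.gct", "expression.tsv", "annotations.csv",
            "survival.csv", "beta.tsv", "cpg_annotations.csv", "arm_cn.tsv",
            "truth.json"]


def _stage_preprocess(cfg, outdir, state):
    cohort = state["cohort"]
    logm = log_transform(cohort.expression, cfg.log_pseudocount)
    corrected = correct_batch(logm, cohort.annotations["batch"])
    state["log_expr"] = corrected
    top = top_variable_genes(corrected, cfg.top_n_genes)
    state["top_genes"] = top
    state["top_expr"] = corrected.subset_genes(top)
    mio.write_matrix_tsv(corrected, outdir / "log2_corrected.tsv")
    pd.Series(top, name="gene_id").to_csv(outdir / "top_genes.csv",
                                          index=False)
    return ["log2_corrected.tsv", "top_genes.csv"]


def _stage_cluster(cfg, outdir, state):
    res = subtype.consensus_cluster(
        state["top_expr"], range(cfg.k_min, cfg.k_max + 1),
        n_resamples=cfg.n_resamples, sample_frac=cfg.sample_frac,
        seed=stage_seed(cfg.seed, "cluster"),
        delta_threshold=cfg.delta_threshold)
    state["consensus"] = res
    k = res.chosen_k
    assign = pd.DataFrame({
        "sample_id": res.sample_ids,
        "cluster": res.assignments[k],
        "silhouette": res.silhouette[k],
    }).set_index("sample_id")
    assign.to_csv(outdir / "assignments.csv")
    pd.DataFrame(res.consensus[k], index=res.sample_ids,
                 columns=res.sample_ids).to_csv(
        outdir / f"consensus_k{k}.tsv", sep="\t",
        float_format=mio.FLOAT_FMT)
    pd.DataFrame({
        "k": sorted(res.cdf_area),
        "cdf_area": [res.cdf_area[k_] for k_ in sorted(res.cdf_area)],
        "delta_area": [res.delta_area[k_] for k_ in sorted(res.cdf_area)],
    }).to_csv(outdir / "cdf_area.csv", index=False,
              float_format=mio.FLOAT_FMT)
    return ["assignments.csv", f"consensus_k{k}.tsv", "cdf_area.csv"]


def _relabel_to_truth(assignments, truth_labels):
    """Map discovered cluster ids onto planted subtype ids by majority
    overlap, so 'subtype 3' downstream means the progressive cluster."""
    assignments = np.asarray(assignments)
    truth_labels = np.asarray(truth_labels)
    mapping = {}
    for c in np.unique(assignments):
        vals, counts = np.unique(truth_labels[assignments == c],
                                 return_counts=True)
        mapping[c] = int(vals[np.argmax(counts)])
    return np.array([mapping[c] for c in assignments])


def _stage_signature(cfg, outdir, state):
    cohort = state["cohort"]
    res = state["consensus"]
    labels = _relabel_to_truth(res.assignments[res.chosen_k],
                               cohort.annotations["subtype"].to_numpy())
    state["cluster_labels"] = labels
    deg = moderated_de(state["log_expr"], labels,
                       target=cfg.progressive_subtype)
    sig = extract_signature(deg, name="progressive",
                            fdr=cfg.fdr, lfc=cfg.lfc)
    if not sig.up or not sig.down:
        # the progression score needs both directions; when one side is
        # empty at the configured fold change (log2(TPM+1) compresses
        # low-abundance effects), fill it at half the threshold
        relaxed = extract_signature(deg, name="progressive",
                                    fdr=cfg.fdr, lfc=cfg.lfc / 2.0)
        sig = SignatureSet("progressive", up=sig.up or relaxed.up,
                           down=sig.down or relaxed.down)
        log.warning("signature side empty at |log2FC| > %.3g; "
                    "filled from |log2FC| > %.3g", cfg.lfc, cfg.lfc / 2.0)
    state["signature"] = sig
    deg.table.to_csv(outdir / "deg_subtype3.tsv", sep="\t",
                     float_format=mio.FLOAT_FMT)
    mio.write_gmt({"PROGRESSIVE_UP": list(sig.up),
                   "PROGRESSIVE_DN": list(sig.down)},
                  outdir / "signature.gmt")
    return ["deg_subtype3.tsv", "signature.gmt"]


def _stage_score(cfg, outdir, state):
    cohort = state["cohort"]
    params = score.SsgseaParams(tau=cfg.tau, normalize=cfg.ssgsea_normalize)
    mp = score.mpscore_table(state["log_expr"], state["signature"], params)
    weights = pd.Series(cohort.truth["stemness_weights"])
    si = score.stemness_index(state["log_expr"], weights)
    imm = score.immune_scores(state["log_expr"],
                              cohort.truth["immune_markers"])
    table = pd.concat([mp, si, imm], axis=1)
    state["scores"] = table
    table.to_csv(outdir / "scores.csv", float_format=mio.FLOAT_FMT)
    return ["scores.csv"]


def _stage_methyl(cfg, outdir, state):
    cohort = state["cohort"]
    labels = pd.Series(state["cluster_labels"],
                       index=cohort.annotations.index)
    cimp = methyl.call_cimp(cohort.methylation, labels,
                            sd_threshold=cfg.cimp_sd_threshold,
                            hyper_beta=cfg.cimp_hyper_beta)
    loss_1p = methyl.call_arm_loss(cohort.arm_cn, "chr1p",
                                   cfg.arm_loss_threshold)
    loss_22q = methyl.call_arm_loss(cohort.arm_cn, "chr22q",
                                    cfg.arm_loss_threshold)
    si = state["scores"]["si"]
    assigned = methyl.assign_methylation_subtype(loss_1p, loss_22q, si,
                                                 cfg.si_threshold)
    out = pd.DataFrame({"cimp_group": labels.map(cimp.to_dict()),
                        "chr1p_loss": loss_1p, "chr22q_loss": loss_22q,
                        "methyl_subtype": assigned})
    state["methyl_assign"] = out
    out.to_csv(outdir / "methyl_assignments.csv")
    cimp.to_csv(outdir / "cimp_flags.csv")
    return ["methyl_assignments.csv", "cimp_flags.csv"]


def _stage_survival(cfg, outdir, state):
    cohort = state["cohort"]
    records = cohort.survival.copy()
    records["event"] = records[cfg.endpoint].astype(int)
    records["mpscore"] = state["scores"]["mpscore"]
    records["mib1"] = cohort.annotations["mib1"]
    groups, cut = surv.dichotomize_mpscore(records["mpscore"])
    lr = surv.logrank_test(records, groups)
    cox = surv.cox_fit(records, ["mpscore", "location", "sex", "mib1"])
    km = surv.km_estimate(records, groups)
    km_rows = []
    for g, tab in km.items():
        t = tab.reset_index(names="time")
        t.insert(0, "group", g)
        km_rows.append(t)
    pd.concat(km_rows).to_csv(outdir / "km_table.csv", index=False,
                              float_format=mio.FLOAT_FMT)
    cox.to_csv(outdir / "cox_table.csv", float_format=mio.FLOAT_FMT)
    (outdir / "survival_tests.json").write_text(json.dumps(
        {"logrank": lr, "mpscore_cutpoint": cut}, indent=2, sort_keys=True))
    state["cox"] = cox
    state["logrank"] = lr
    return ["km_table.csv", "cox_table.csv", "survival_tests.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "cluster": _stage_cluster,
    "signature": _stage_signature,
    "score": _stage_score,
    "methyl-assign": _stage_methyl,
    "survival": _stage_survival,
}
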