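"""Stage orchestration: run the analyses as one reproducible pipeline.

A :class:`RunConfig` (YAML or JSON on disk) names the inputs, the stages
to run and their parameters; defaults are the published settings (20,000
F_ST permutations, HWE alpha 0.05, 50+50-allele projection,
mu = 7.5e-9, 50 ECM rounds, 50 bootstrap replicates).  Every random stage
receives a seed derived deterministically from the global seed, recorded
in the summary, so identical config + seed reproduces all numbers
exactly.  A stage failure halts its dependents and the run is marked
partial.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

STAGE_ORDER = ["ecomorph", "fst", "sfs", "fit", "bootstrap"]
DEPENDS = {"bootstrap": "fit"}

DEFAULT_PARAMS = dict(
    n_permutations=20_000,
    hwe_alpha=0.05,
    max_snps_per_tag=3,
    projection=(50, 50),
    mu=7.5e-9,
    effective_length=3.78e6,
    ecm_rounds=50,
    sims_start=100_000,
    sims_end=250_000,
    sims_step=5_000,
    n_starts=5,
    n_bootstrap=50,
)


@dataclass
class RunConfig:
    stages: List[str]
    out_dir: str
    seed: int = 0
    inputs: Dict[str, str] = field(default_factory=dict)
    params: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        merged = dict(DEFAULT_PARAMS)
        merged.update(self.params)
        self.params = merged
        for key, p in self.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input {key!r}: no such file {p}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)  # YAML is a superset of JSON
        return cls(
            stages=raw.get("stages", list(STAGE_ORDER)),
            out_dir=raw.get("out_dir", "craterdemog_out"),
            seed=int(raw.get("seed", 0)),
            inputs=raw.get("inputs", {}) or {},
            params=raw.get("params", {}) or {},
        )

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, STAGE_ORDER.index(stage)])
        return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _stage_ecomorph(cfg: RunConfig, out: Path) -> dict:
    import pandas as pd

    from .ecomorph import anova_oneway, lipid_correct_d13c, manova_pillai, welch_t
    from .io import read_specimen_table

    if "specimen_table" in cfg.inputs:
        specimens, rejected = read_specimen_table(cfg.inputs["specimen_table"])
    else:
        from .synth import FieldSimConfig, gen_specimen_table

        specimens = gen_specimen_table(
            FieldSimConfig(seed=cfg.stage_seed("ecomorph"))
        )
        rejected = []
    groups: Dict[str, list] = {"limnetic": [], "benthic": []}
    iso: Dict[str, list] = {"limnetic": [], "benthic": []}
    for s in specimens:
        if s.bhi is not None:
            groups[s.habitat].append(s.bhi)
        if s.d13c_raw is not None and s.d15n is not None:
            d13c = (
                lipid_correct_d13c(s.d13c_raw, s.c_n_ratio)
                if s.c_n_ratio is not None
                else s.d13c_raw
            )
            iso[s.habitat].append((d13c, s.d15n))
    results = []
    t = welch_t(groups["limnetic"], groups["benthic"])
    results.append(("bhi_welch_t", t.statistic, t.df, t.p_value))
    obs = np.array(iso["limnetic"] + iso["benthic"])
    labels = ["limnetic"] * len(iso["limnetic"]) + ["benthic"] * len(iso["benthic"])
    if len(iso["limnetic"]) >= 3 and len(iso["benthic"]) >= 3:
        man = manova_pillai(obs, labels)
        results.append(("isotope_manova_pillai", man.statistic, man.df, man.p_value))
        for col, nm in ((0, "d13c"), (1, "d15n")):
            a = anova_oneway(obs[:, col], labels)
            results.append((f"{nm}_anova_F", a.statistic, a.df, a.p_value))
    df = pd.DataFrame(results, columns=["test", "statistic", "df", "p_value"])
    df.to_csv(out / "ecomorph_tests.tsv", sep="\t", index=False)
    return dict(
        n_specimens=len(specimens),
        n_rejected_rows=len(rejected),
        mean_bhi_limnetic=float(np.mean(groups["limnetic"])),
        mean_bhi_benthic=float(np.mean(groups["benthic"])),
        tests={r[0]: {"statistic": r[1], "p": r[3]} for r in results},
    )


def _stage_fst(cfg: RunConfig, out: Path) -> dict:
    import pandas as pd

    from .io import read_microsat_table
    from .popgen import fst_permutation_test

    if "microsat_table" in cfg.inputs:
        table = read_microsat_table(cfg.inputs["microsat_table"])
    else:
        from .synth import gen_microsat_genotypes

        table = gen_microsat_genotypes(seed=cfg.stage_seed("fst"))
    res = fst_permutation_test(
        table,
        n_perm=int(cfg.params["n_permutations"]),
        seed=cfg.stage_seed("fst"),
    )
    pd.DataFrame(
        [{"locus": k, "theta": v} for k, v in res.per_locus.items()]
        + [{"locus": "overall", "theta": res.theta}]
    ).to_csv(out / "fst.tsv", sep="\t", index=False)
    return dict(theta=res.theta, p_value=res.p_value, n_permutations=res.n_permutations)


def _stage_sfs(cfg: RunConfig, out: Path) -> dict:
    import pandas as pd

    from .io import read_vcf_genotypes, write_sfs
    from .sfs import build_joint_minor_sfs, filter_rad_snps, project_sfs

    if "vcf" not in cfg.inputs:
        raise ValueError("sfs stage requires inputs.vcf")
    populations = None
    if "pop_map" in cfg.inputs:
        pm = pd.read_csv(cfg.inputs["pop_map"], sep="\t", header=None)
        populations = dict(zip(pm[0], pm[1]))
    blacklist = None
    if "blacklist" in cfg.inputs:
        blacklist = set(Path(cfg.inputs["blacklist"]).read_text().split())
    table = read_vcf_genotypes(cfg.inputs["vcf"], populations=populations)
    filtered, report = filter_rad_snps(
        table,
        hwe_alpha=float(cfg.params["hwe_alpha"]),
        max_snps_per_tag=int(cfg.params["max_snps_per_tag"]),
        blacklist=blacklist,
    )
    sfs = build_joint_minor_sfs(
        filtered, effective_length=float(cfg.params["effective_length"])
    )
    p1, p2 = cfg.params["projection"]
    sfs = project_sfs(sfs, int(p1), int(p2))
    write_sfs(sfs, out / "joint_sfs.txt")
    pd.DataFrame([report.as_dict()]).to_csv(
        out / "filter_report.tsv", sep="\t", index=False
    )
    return dict(
        filter=report.as_dict(),
        n_polymorphic=sfs.n_polymorphic,
        projection=[int(p1), int(p2)],
    )


def _stage_fit(cfg: RunConfig, out: Path, state: dict) -> dict:
    from .fit import crater_model_spec, ecm_fit
    from .io import read_sfs
    from .types import InferenceConfig

    obs_path = cfg.inputs.get("obs_sfs") or str(Path(cfg.out_dir) / "joint_sfs.txt")
    obs = read_sfs(obs_path)
    spec = crater_model_spec(samples=(obs.n1, obs.n2))
    icfg = InferenceConfig(
        mu=float(cfg.params["mu"]),
        ecm_rounds=int(cfg.params["ecm_rounds"]),
        sims_start=int(cfg.params["sims_start"]),
        sims_end=int(cfg.params["sims_end"]),
        sims_step=int(cfg.params["sims_step"]),
        n_starts=int(cfg.params["n_starts"]),
        seed=cfg.stage_seed("fit"),
    )
    fit_result = ecm_fit(spec, obs, icfg)
    state["fit"] = (spec, fit_result, obs, icfg)
    payload = dict(
        model_id=fit_result.model_id,
        params=fit_result.params,
        lnl=fit_result.lnl,
        aic=fit_result.aic,
    )
    (out / "fit.json").write_text(json.dumps(payload, indent=2))
    return payload


def _stage_bootstrap(cfg: RunConfig, out: Path, state: dict) -> dict:
    from .fit import parametric_bootstrap

    spec, fit_result, obs, icfg = state["fit"]
    ci = parametric_bootstrap(
        spec,
        fit_result,
        effective_length=float(cfg.params["effective_length"]),
        config=icfg,
        n_boot=int(cfg.params["n_bootstrap"]),
    )
    (out / "bootstrap_ci.json").write_text(json.dumps(ci, indent=2))
    return {k: list(v) for k, v in ci.items()}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the machine-readable run report (also written to
    ``summary.json``): per-stage outputs, seeds and parameters, with
    ``status`` "ok", "partial" (some stage failed) or the failure detail.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "params": {}, "stages": {}, "status": "ok"}
    report["params"] = {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.params.items()
    }
    failed: set = set()
    state: dict = {}
    for stage in STAGE_ORDER:
        if stage not in cfg.stages:
            continue
        dep = DEPENDS.get(stage)
        if dep and (dep in failed or dep not in state):
            report["stages"][stage] = {
                "status": "skipped",
                "reason": f"dependency {dep!r} failed or did not run",
            }
            report["status"] = "partial"
            continue
        logger.info("running stage %s (seed %d)", stage, cfg.stage_seed(stage))
        try:
            if stage == "ecomorph":
                res = _stage_ecomorph(cfg, out)
            elif stage == "fst":
                res = _stage_fst(cfg, out)
            elif stage == "sfs":
                res = _stage_sfs(cfg, out)
            elif stage == "fit":
                res = _stage_fit(cfg, out, state)
            else:
                res = _stage_bootstrap(cfg, out, state)
            report["stages"][stage] = {
                "status": "ok",
                "seed": cfg.stage_seed(stage),
                "result": res,
            }
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.exception("stage %s failed", stage)
            failed.add(stage)
            report["stages"][stage] = {"status": "failed", "error": str(exc)}
            report["status"] = "partial"
    (out / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
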