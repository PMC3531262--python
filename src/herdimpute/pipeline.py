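"""Configuration-driven orchestration of full benchmark runs.

A run executes: simulate population -> QC + panel construction ->
scenario reference/test splits with masking -> HMM imputation (2- or
3-tier) + sampling baseline -> error evaluation (incl. kinship and sire
stratifications) -> SNP-BLUP prediction comparison. All artifacts are
written under the output directory and inventoried, with checksums, in a
manifest sufficient to reproduce the run bit for bit.

Per-stage seeds are derived from the master seed as
``sha256(f"{seed}:{stage}") mod 2**31`` so any stage can be reproduced in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .evaluation import (Scenario, SelectionRule, error_report,
                         mask_genotypes, pedigree_kinship,
                         sire_in_reference_comparison, split_reference_test,
                         stratify_error_by_kinship)
from .imputation import HmmConfig, impute_diploid, impute_tiered, \
    sampling_baseline
from .io import write_map, write_pedigree, write_phenotypes, write_vcf
from .panels import SnpPanel, QcThresholds, panel_maf, qc_filter, thin_evenly
from .prediction import SnpBlup, cross_validate_lambda, dgv_accuracy
from .simdata import (MISSING, GenomeMap, TraitSpec, apply_genotyping,
                      gene_drop, simulate_founder_haplotypes,
                      simulate_pedigree, simulate_phenotypes)

log = logging.getLogger("herdimpute")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: sha256 of '<seed>:<stage>' mod 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest, 16) % (2**31)


@dataclass
class RunConfig:
    """Validated run configuration (see ``RunConfig.from_yaml``)."""

    seed: int
    outdir: str
    simulation: dict = field(default_factory=dict)
    panels: list = field(default_factory=list)
    hmm: dict = field(default_factory=dict)
    scenarios: list = field(default_factory=list)
    prediction: dict | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ValueError("config must specify a master seed")
        cfg = cls(seed=int(raw["seed"]), outdir=str(raw.get("outdir", "out")),
                  simulation=dict(raw.get("simulation", {})),
                  panels=list(raw.get("panels", [])),
                  hmm=dict(raw.get("hmm", {})),
                  scenarios=list(raw.get("scenarios", [])),
                  prediction=raw.get("prediction"))
        names = {p["name"] for p in cfg.panels} | {"full"}
        for sc in cfg.scenarios:
            if "name" not in sc or "reference" not in sc:
                raise ValueError("each scenario needs 'name' and 'reference'")
            panel = sc.get("typed_panel")
            if panel is not None and panel not in names:
                raise ValueError(f"scenario {sc['name']!r} references "
                                 f"undefined panel {panel!r}")
        HmmConfig(**cfg.hmm)  # validates
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {"seed": self.seed, "outdir": self.outdir,
                "simulation": self.simulation, "panels": self.panels,
                "hmm": self.hmm, "scenarios": self.scenarios,
                "prediction": self.prediction}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict
    version: str
    files: dict  # path -> sha256

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True)
                        + "\n")


def _scenario_from_dict(sc: dict) -> Scenario:
    def rule(d):
        return SelectionRule(**d) if d is not None else None
    return Scenario(name=sc["name"], reference=SelectionRule(**sc["reference"]),
                    test=rule(sc.get("test")),
                    typed_panel=sc.get("typed_panel"),
                    mask=sc.get("mask", {"type": "complement"}))


def default_config(seed: int = 0, outdir: str = "out") -> RunConfig:
    """Bundled benchmark-mimic configuration at desk scale: a pedigreed
    population, nested low/medium/high panels with density ratios echoing
    3K/7K/50K chips, a 50% reference scenario, and a prediction comparison
    of true, imputed and low-density genotypes for an h^2 = 0.25 trait."""
    return RunConfig.from_dict({
        "seed": seed,
        "outdir": outdir,
        "simulation": {
            "n_founders": 60, "n_generations": 4,
            "mating_design": {"sires_per_generation": 5,
                              "offspring_per_generation": 60},
            "n_chromosomes": 2, "markers_per_chromosome": 300,
            "n_ancestral": 20, "mosaic_switch_rate": 1.0,
            "missing_rate": 0.005, "error_rate": 0.0},
        "panels": [{"name": "medium", "size": 80},
                   {"name": "low", "size": 36}],
        "hmm": {"ne": 100, "error_rate": 0.005,
                "max_reference_haplotypes": 200},
        "scenarios": [{"name": "ref50_low",
                       "reference": {"fraction": 0.5},
                       "typed_panel": "low"}],
        "prediction": {"trait": {"name": "milk", "heritability": 0.25,
                                 "n_causal": 50},
                       "reliability_range": [0.3, 0.9],
                       "n_folds": 4,
                       "validation_fraction": 0.25,
                       "typed_panel": "low"},
    })


def run_scenario(config: RunConfig) -> RunManifest:
    """Execute a full configured run and return its manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    events = []

    def stage(name):
        t = time.time()
        log.info("stage %s started", name)
        events.append({"stage": name, "time": t})
        return t

    seeds = {s: stage_seed(config.seed, s) for s in
             ("pedigree", "founders", "genedrop", "assay", "split",
              "baseline", "phenotypes", "cv", "mask")}
    files: dict[str, str] = {}

    def emit(path: Path):
        files[str(path.relative_to(out))] = _sha256(path)

    # --- simulate ---------------------------------------------------------
    stage("simulate")
    sim = config.simulation
    gmap = GenomeMap.uniform(int(sim.get("n_chromosomes", 2)),
                             int(sim.get("markers_per_chromosome", 300)))
    ped = simulate_pedigree(int(sim.get("n_founders", 60)),
                            int(sim.get("n_generations", 4)),
                            sim.get("mating_design"), seeds["pedigree"])
    pool, founders = simulate_founder_haplotypes(
        gmap, sim.get("maf_spectrum"),
        int(sim.get("n_ancestral", 20)),
        float(sim.get("mosaic_switch_rate", 1.0)),
        n_founders=int(np.sum(ped.is_founder)), seed=seeds["founders"])
    pop = gene_drop(ped, founders, gmap, seeds["genedrop"])
    assay = apply_genotyping(pop, np.arange(gmap.n_markers),
                             float(sim.get("missing_rate", 0.0)),
                             float(sim.get("error_rate", 0.0)),
                             seeds["assay"])
    write_pedigree(out / "pedigree.tsv", ped)
    emit(out / "pedigree.tsv")
    write_map(out / "map.tsv", gmap)
    emit(out / "map.tsv")
    write_vcf(out / "truth.vcf", gmap, pop.animal_ids,
              haplotypes=pop.haplotypes)
    emit(out / "truth.vcf")

    # --- panels -----------------------------------------------------------
    stage("panels")
    qc = qc_filter(assay, QcThresholds(), ped, gmap.marker_id)
    qc.report.to_csv(out / "qc_report.csv", index=False)
    emit(out / "qc_report.csv")
    high = SnpPanel.from_indices(gmap, "high", qc.kept)
    high_maf = panel_maf(qc.genotypes)
    panels = {"full": SnpPanel.full(gmap), "high": high}
    for spec_p in config.panels:
        size = spec_p.get("size")
        if size is None:
            continue
        panels[spec_p["name"]] = thin_evenly(gmap, high_maf, int(size),
                                             source=high,
                                             name=spec_p["name"])
    for name, p in panels.items():
        df = [(gmap.chrom[i], gmap.marker_id[i]) for i in p.indices]
        import pandas as pd
        pd.DataFrame(df, columns=["chrom", "marker_id"]).to_csv(
            out / f"panel_{name}.tsv", sep="\t", index=False)
        emit(out / f"panel_{name}.tsv")

    # column positions of each panel inside the high panel
    hi_pos = {int(m): k for k, m in enumerate(high.indices)}
    hmm_cfg = HmmConfig(**config.hmm)
    kinship = pedigree_kinship(ped)
    truth_high = pop.genotypes[:, high.indices].astype(np.int8)
    hi_cm = gmap.cm[high.indices]
    hi_chrom = gmap.chrom[high.indices]

    # --- scenarios --------------------------------------------------------
    results = {}
    if not config.scenarios:
        log.warning("empty scenario list; writing manifest only")
    for sc_dict in config.scenarios:
        sc = _scenario_from_dict(sc_dict)
        stage(f"scenario:{sc.name}")
        ref_idx, test_idx = split_reference_test(
            ped, sc, stage_seed(config.seed, f"split:{sc.name}"))
        ref_h = pop.haplotypes[ref_idx][:, :, high.indices]
        ref_h = ref_h.reshape(-1, len(high))
        test_g = truth_high[test_idx]
        if sc.mask.get("type") == "every_nth":
            typed = ("every_nth", int(sc.mask["n"]))
            masked_g, store = mask_genotypes(
                test_g, typed, float(sc.mask.get("animal_fraction", 1.0)),
                stage_seed(config.seed, f"mask:{sc.name}"))
        else:
            panel = panels[sc.typed_panel or "high"]
            typed_cols = np.array([hi_pos[int(m)] for m in panel.indices
                                   if int(m) in hi_pos])
            masked_g, store = mask_genotypes(test_g, typed_cols)
        res = impute_diploid(masked_g, ref_h, hmm_cfg,
                             genetic_pos_cm=hi_cm, chrom=hi_chrom)
        rep = error_report(res.best_guess, store,
                           [pop.animal_ids[i] for i in test_idx], hi_chrom)
        freq = ref_h.mean(axis=0)
        base = sampling_baseline(store.masked, freq,
                                 stage_seed(config.seed, f"base:{sc.name}"))
        base_rep = error_report(np.where(store.masked, base, store.truth),
                                store)
        strat = stratify_error_by_kinship(
            rep.per_animal["allelic_error"].to_numpy(), kinship, ref_idx,
            test_idx)
        sire_cmp = sire_in_reference_comparison(
            rep.per_animal["allelic_error"].to_numpy(), ped, ref_idx,
            test_idx)
        rep.per_animal.to_csv(out / f"errors_{sc.name}_per_animal.csv",
                              index=False)
        emit(out / f"errors_{sc.name}_per_animal.csv")
        strat.to_csv(out / f"errors_{sc.name}_by_kinship.csv", index=False)
        emit(out / f"errors_{sc.name}_by_kinship.csv")
        summary = {
            "allelic_error": rep.allelic_error,
            "genotypic_error": rep.genotypic_error,
            "n_genotypes": rep.n_genotypes,
            "baseline_allelic_error": base_rep.allelic_error,
            "n_reference": int(len(ref_idx)),
            "n_test": int(len(test_idx)),
            "sire_comparison": sire_cmp.to_dict("records"),
        }
        results[sc.name] = summary
        (out / f"errors_{sc.name}.json").write_text(
            json.dumps(summary, indent=2) + "\n")
        emit(out / f"errors_{sc.name}.json")
        log.info("scenario %s: allelic %.3f%%, genotypic %.3f%%, "
                 "baseline %.3f%%", sc.name, rep.allelic_error,
                 rep.genotypic_error, base_rep.allelic_error)

    # --- prediction -------------------------------------------------------
    if config.prediction:
        stage("predict")
        pc = config.prediction
        trait = TraitSpec(**pc.get("trait", {"name": "trait",
                                             "heritability": 0.25,
                                             "n_causal": 50}))
        phen = simulate_phenotypes(pop, trait,
                                   tuple(pc.get("reliability_range",
                                                (0.3, 0.9))),
                                   seeds["phenotypes"])
        write_phenotypes(out / "phenotypes.tsv", phen.records)
        emit(out / "phenotypes.tsv")
        rng = np.random.default_rng(stage_seed(config.seed, "predsplit"))
        n = pop.n_animals
        val_n = int(round(float(pc.get("validation_fraction", 0.25)) * n))
        perm = rng.permutation(n)
        val_idx, train_idx = perm[:val_n], perm[val_n:]

        panel = panels[pc.get("typed_panel", "low")]
        typed_cols = np.array([hi_pos[int(m)] for m in panel.indices
                               if int(m) in hi_pos])
        masked_val, _ = mask_genotypes(truth_high[val_idx], typed_cols)
        ref_h = pop.haplotypes[train_idx][:, :, high.indices]
        res = impute_diploid(masked_val, ref_h.reshape(-1, len(high)),
                             hmm_cfg, genetic_pos_cm=hi_cm, chrom=hi_chrom)
        X_train = truth_high[train_idx].astype(float)
        lam, _ = cross_validate_lambda(
            X_train, phen.dtd[train_idx], phen.reliability[train_idx],
            n_folds=int(pc.get("n_folds", 4)), seed=seeds["cv"],
            heritability=trait.heritability)
        model = SnpBlup(lam=lam).fit(X_train, phen.dtd[train_idx],
                                     phen.reliability[train_idx])
        acc = {
            "lambda": lam,
            "accuracy_true": dgv_accuracy(
                model.predict(truth_high[val_idx].astype(float)),
                phen.dtd[val_idx]),
            "accuracy_imputed": dgv_accuracy(
                model.predict(res.best_guess.astype(float)),
                phen.dtd[val_idx]),
            "accuracy_dosage": dgv_accuracy(model.predict(res.dosage),
                                            phen.dtd[val_idx]),
        }
        low_model = SnpBlup(lam=lam * len(typed_cols) / len(high)).fit(
            X_train[:, typed_cols], phen.dtd[train_idx],
            phen.reliability[train_idx])
        acc["accuracy_low_density"] = dgv_accuracy(
            low_model.predict(truth_high[val_idx][:, typed_cols].astype(float)),
            phen.dtd[val_idx])
        results["prediction"] = acc
        (out / "prediction.json").write_text(json.dumps(acc, indent=2) + "\n")
        emit(out / "prediction.json")
        log.info("prediction accuracies: %s", acc)

    # --- manifest ---------------------------------------------------------
    stage("manifest")
    (out / "summary.json").write_text(json.dumps(results, indent=2,
                                                 sort_keys=True) + "\n")
    emit(out / "summary.json")
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    (out / "run.log.json").write_text(json.dumps(events, indent=2) + "\n")
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest(),
        seed=config.seed, stage_seeds=seeds, version=__version__,
        files=files)
    manifest.write(out / "manifest.json")
    return manifest


def setup_logging(level: str = "INFO", logfile: Path | None = None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers, force=True)
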