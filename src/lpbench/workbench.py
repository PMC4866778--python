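"""End-to-end pipelines and reduced-scale presets.

``make_toy_system`` builds the study systems: ``cube2`` (the 2x2x2 box with
a reduced HP-like alphabet, small enough for exact enumeration of sequence
space), ``minipool`` (3x3x3 box, 50 seeded folds, full 20-letter alphabet)
and ``fullscale`` (3x3x3, 10,000 seeded folds; hours
of CPU when sampled at full depth).

``run_benchmark`` composes the pipeline sample -> infer -> score ->
classify -> generate for one native fold and returns a report of PPV
values, design-pressure class means and generative-quality summaries.
Every artifact carries the configuration hash; re-running a stage whose
artifact already exists reloads it instead of recomputing.
"""

from __future__ import annotations

import functools
import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import contact_scoring as cs
from . import msa_statistics as ms
from .energetics import ContactEnergyMatrix, competitor_profile, load_mj_matrix
from .generative_eval import evaluate_generated, sample_from_model
from .lattice_conformations import StructureLibrary, enumerate_compact_folds
from .potts_inference import infer_ace, infer_dca_meanfield, infer_im, infer_plm
from .sequence_sampler import AlignmentSet, SamplerConfig, metropolis_chain

__all__ = ["BenchmarkConfig", "make_toy_system", "run_benchmark", "hp_energy_matrix"]


def hp_energy_matrix(q: int = 2) -> ContactEnergyMatrix:
    """Reduced hydrophobic-polar contact energies for toy alphabets.

    H-H contacts are strongly favourable, H-P weakly so, P-P neutral; the
    optional third letter N is nearly inert.  Units follow the MJ table
    (RT, unit temperature).
    """
    if q == 2:
        return ContactEnergyMatrix("HP", np.array([[-2.3, -1.0], [-1.0, 0.0]]))
    if q == 3:
        return ContactEnergyMatrix(
            "HPN",
            np.array(
                [
                    [-2.3, -1.0, -0.3],
                    [-1.0, 0.0, -0.1],
                    [-0.3, -0.1, -0.05],
                ]
            ),
        )
    raise ValueError("cube2 preset supports q = 2 or 3")


@functools.lru_cache(maxsize=4)
def _full_enumeration(box: tuple, include_reversal: bool) -> StructureLibrary:
    return enumerate_compact_folds(box, include_reversal=include_reversal)


def make_toy_system(
    preset: str, q: int = 2, seed: int = 0
) -> tuple[StructureLibrary, ContactEnergyMatrix, SamplerConfig]:
    """Preset (library, energy matrix, sampler defaults); deterministic per seed."""
    if preset == "cube2":
        lib = enumerate_compact_folds((2, 2, 2))
        E = hp_energy_matrix(q)
        config = SamplerConfig(
            n_samples=1000, beta=10.0, interval=10, pnat_threshold=0.0, seed=seed
        )
        return lib, E, config
    if preset == "minipool":
        lib = _full_enumeration((3, 3, 3), False).subsample(50, seed=seed)
        return lib, load_mj_matrix(), SamplerConfig(
            n_samples=2000, beta=1e3, interval=1000, seed=seed
        )
    if preset == "fullscale":
        lib = _full_enumeration((3, 3, 3), False).subsample(10_000, seed=seed)
        return lib, load_mj_matrix(), SamplerConfig(
            n_samples=50_000, beta=1e3, interval=1000, seed=seed
        )
    raise ValueError(f"unknown preset {preset!r}")


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of one benchmark run (flat key-value semantics)."""

    preset: str = "minipool"
    q: int = 20  # used by the cube2 preset only
    native_index: int = 0
    n_samples: int = 2000
    beta: float = 1e3
    interval: int = 1000
    identity_cutoff: float = 0.0
    methods: tuple = ("mi", "plm", "ace")
    n_generate: int = 500
    seed: int = 0
    outdir: Optional[str] = None

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=list).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_benchmark(config: BenchmarkConfig) -> dict:
    """Sample an MSA, infer the requested models, score contacts, classify
    pair pressures and test generative quality; returns the report dict
    (also written as JSON, with a manifest, when ``outdir`` is set)."""
    if config.preset == "cube2" and config.q not in (2, 3):
        raise ValueError("cube2 preset requires q in (2, 3)")
    chash = config.config_hash()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        report_path = outdir / f"report_{chash}.json"
        if report_path.exists():
            return json.loads(report_path.read_text())

    lib, E, sampler_defaults = make_toy_system(config.preset, q=config.q, seed=config.seed)
    if not 0 <= config.native_index < lib.N:
        raise ValueError(f"native index {config.native_index} outside library of {lib.N}")
    scfg = replace(
        sampler_defaults,
        n_samples=config.n_samples,
        beta=config.beta,
        interval=config.interval,
        seed=config.seed,
    )

    msa_path = outdir / f"msa_{chash}.fasta" if outdir else None
    if msa_path is not None and msa_path.exists():
        msa = AlignmentSet.read_fasta(msa_path, E.alphabet)
    else:
        msa = metropolis_chain(config.native_index, lib, E, scfg)
        if msa_path is not None:
            msa.write_fasta(msa_path)

    weights, m_eff = ms.sequence_weights(msa, config.identity_cutoff)
    stats = ms.frequencies(msa, weights)
    consensus, identity = ms.consensus_and_identity(msa)
    native_cmap = lib.contact_map(config.native_index)
    n_contacts = len(native_cmap)

    report: dict = {
        "config_hash": chash,
        "preset": config.preset,
        "native_index": config.native_index,
        "M": msa.M,
        "M_eff": m_eff,
        "mean_identity_pct": identity,
        "n_contacts": n_contacts,
        "top_eigenvalue": cs.contact_matrix_top_eigenvalue(native_cmap),
        "ppv_at_n_contacts": {},
        "log": {"burnin_steps": msa.provenance.get("burnin_steps"),
                "sampler_seed": config.seed},
    }

    models = {}
    score_sets = {}
    if "mi" in config.methods:
        score_sets["mi"] = cs.mi_apc_scores(ms.mutual_information_scores(stats))
    if "dca" in config.methods:
        stats_pc = ms.frequencies(msa, weights, pseudocount=0.5)
        models["dca"] = infer_dca_meanfield(stats_pc)
        score_sets["dca"] = cs.frobenius_apc_scores(models["dca"])
    if "plm" in config.methods:
        models["plm"] = infer_plm(msa, weights, gamma=0.01)
        score_sets["plm"] = cs.frobenius_apc_scores(models["plm"])
    if "ace" in config.methods:
        models["ace"], entropy = infer_ace(msa, weights, seed=config.seed)
        score_sets["ace"] = cs.frobenius_apc_scores(models["ace"])
        report["ace_entropy"] = entropy.entropy
        report["ace_entropy_converged"] = entropy.converged

    # projection scoring and pressure classes from the best available model
    proj_source = "ace" if "ace" in models else ("plm" if "plm" in models else None)
    if proj_source is not None:
        pressure_map = cs.pressures(models[proj_source], E, stats)
        score_sets["projection"] = pressure_map.score_matrix()
        profile = competitor_profile(config.native_index, lib, msa.sequences, E)
        sf_cmap = lib.contact_map(profile.closest_competitor)
        classes = cs.classify_pairs(native_cmap, sf_cmap)
        pressure_map.classes = classes.labels
        report["closest_competitor"] = profile.closest_competitor
        report["aggregate_competitor_weight"] = profile.aggregate
        report["class_counts"] = classes.counts()
        report["pressure_class_means"] = {
            label: pressure_map.class_mean(label) for label in ("UN", "SN", "CC", "NN")
        }
        report["mean_pressure_native_contacts"] = float(
            np.mean([pressure_map.lam[i, j] for (i, j) in native_cmap.pairs])
        )

    for name, scores in score_sets.items():
        ppv = cs.ppv_curve(scores, native_cmap)
        report["ppv_at_n_contacts"][name] = float(ppv[n_contacts - 1])

    # generative check: Potts-sampled vs independent-site-sampled sequences
    gen_source = "ace" if "ace" in models else ("plm" if "plm" in models else None)
    if gen_source is not None and config.n_generate > 0:
        stats_im = ms.frequencies(msa, weights, pseudocount=1e-3)
        im_model = infer_im(stats_im)
        im_model.meta["alphabet"] = E.alphabet
        gen_potts = sample_from_model(
            models[gen_source], config.n_generate, seed=config.seed + 7
        )
        gen_im = sample_from_model(im_model, config.n_generate, seed=config.seed + 8)
        ev_potts = evaluate_generated(
            gen_potts, config.native_index, lib, E, consensus, models[gen_source]
        )
        ev_im = evaluate_generated(gen_im, config.native_index, lib, E, consensus)
        report["generated_median_pnat"] = {
            "potts": ev_potts.median_pnat,
            "im": ev_im.median_pnat,
        }
        report["generated_mean_distance"] = {
            "potts": ev_potts.mean_distance,
            "im": ev_im.mean_distance,
        }

    report = _round_floats(report)
    if outdir is not None:
        manifest = {
            "config": _round_floats(asdict(config)),
            "config_hash": chash,
            "library_hash": lib.manifest_hash(),
            "package": "lpbench 0.1.0",
        }
        (outdir / f"manifest_{chash}.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=list)
        )
        (outdir / f"report_{chash}.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report
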