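"""End-to-end orchestration: structure dynamics + coevolution + synthesis.

A :class:`RunConfig` collects every tunable parameter of the analysis
with its documented default, serialises to/from YAML, and drives three
entry points:

* :func:`run_dynamics` — structure → GNM mobility/hinges → ANM/PRS
  effector-sensor analysis, with per-residue influence and sensitivity
  profiles for configured target residues (by default the linker
  residues and the detected hinges).
* :func:`run_coevolution` — alignment → redundancy weighting → the
  five coevolution scorers → interdomain submatrices, consensus pair
  table and cumulative propensity profiles.
* :func:`run_all` — both, merged with a per-residue evidence summary
  cross-referencing hinges and consensus pairs against PRS marginals
  and conservation entropy.

Every run writes a JSON manifest of the full configuration; rerunning
from the same manifest reproduces all numeric outputs exactly (the one
master seed is split per stage).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .coevolution import CoevolutionResult, run_method
from .gnm import build_gnm, cumulative_mobility, decompose_gnm, dynamics_fraction, find_hinges
from .integration import (
    annotate_contacts,
    consensus_pairs,
    cumulative_propensity,
    interdomain_submatrix,
    write_consensus_table,
)
from .msa import filter_columns, map_to_reference, read_msa, sequence_weights, shannon_entropy
from .prs import build_anm, influence_profile, prs_map, rank_effectors_sensors, response_profile
from .structure import (
    DNAK_DOMAIN_MAP,
    DNAK_NBD_RANGE,
    DNAK_SBD_RANGE,
    DomainMap,
    annotate_domains,
    read_structure,
    write_residue_table,
)

__all__ = ["RunConfig", "run_dynamics", "run_coevolution", "run_all"]


@dataclass
class RunConfig:
    """All parameters of a full analysis run, with documented defaults."""

    # inputs
    structure_path: str | None = None
    chain: str | None = None
    msa_path: str | None = None
    msa_format: str = "fasta"
    reference_id: str | None = None
    reference_start: int = 1
    # domain partition: label -> list of [lo, hi] closed intervals;
    # None selects the bundled DnaK map
    domain_segments: dict | None = None
    group_a: tuple[int, int] = DNAK_NBD_RANGE
    group_b: tuple[int, int] = DNAK_SBD_RANGE
    # dynamics
    gnm_cutoff: float = 7.3
    anm_cutoff: float = 13.0
    n_modes: int = 10
    hinge_window: int = 5
    hinge_percentile: float = 20.0
    prs_mode: str = "closed_form"
    prs_trials: int = 1000
    top_n: int = 10
    target_residues: list[int] | None = None
    # coevolution
    methods: tuple[str, ...] = ("MIp", "OMES", "SCA", "DI", "PSICOV")
    identity_threshold: float = 0.8
    max_gap_fraction: float = 0.5
    top_fraction: float = 0.0006
    k_override: int | None = None
    min_methods: int = 2
    # bookkeeping
    seed: int = 0
    output_dir: str = "allomap_out"

    def domain_map(self) -> DomainMap:
        if self.domain_segments is None:
            return DNAK_DOMAIN_MAP
        return DomainMap(
            {
                label: tuple((int(lo), int(hi)) for lo, hi in ranges)
                for label, ranges in self.domain_segments.items()
            }
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.group_a, list):
            cfg.group_a = tuple(cfg.group_a)
        if isinstance(cfg.group_b, list):
            cfg.group_b = tuple(cfg.group_b)
        if isinstance(cfg.methods, list):
            cfg.methods = tuple(cfg.methods)
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_a"] = list(d["group_a"])
        d["group_b"] = list(d["group_b"])
        d["methods"] = list(d["methods"])
        return d


def _write_manifest(config: RunConfig, outdir: Path, stage: str, extra: dict) -> None:
    manifest = {
        "stage": stage,
        "allomap_version": __version__,
        "config": config.as_dict(),
        **extra,
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _write_profile(path: Path, residue_ids, labels, values) -> None:
    with open(path, "w") as fh:
        fh.write("residue_id\tlabel\tvalue\n")
        for rid, lab, val in zip(residue_ids, labels, values):
            fh.write(f"{rid}\t{lab}\t{val:.8g}\n")


def run_dynamics(config: RunConfig) -> dict:
    """Structure → GNM mobility/hinges + PRS effector/sensor analysis."""
    if not config.structure_path or not Path(config.structure_path).exists():
        raise FileNotFoundError(
            f"structure file not found: {config.structure_path!r} (dynamics stage)"
        )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dmap = config.domain_map()
    model = annotate_domains(
        read_structure(config.structure_path, config.chain), dmap
    )
    write_residue_table(model, outdir / "residues.tsv")

    net = build_gnm(model, cutoff=config.gnm_cutoff)
    modes = decompose_gnm(net)
    m = min(config.n_modes, modes.n_nonzero)
    profile = cumulative_mobility(modes, m)
    hinges = find_hinges(profile, config.hinge_window, config.hinge_percentile)
    frac = dynamics_fraction(modes, m)
    _write_profile(outdir / "mobility.tsv", model.residue_ids, model.labels, profile.values)

    anm = build_anm(model, cutoff=config.anm_cutoff)
    pmap = prs_map(
        anm,
        mode=config.prs_mode,
        m_trials=config.prs_trials,
        seed=config.seed,
    )
    effectors, sensors, overlap = rank_effectors_sensors(pmap, config.top_n)
    _write_profile(
        outdir / "prs_marginals.tsv",
        model.residue_ids,
        model.labels,
        pmap.effectiveness,
    )

    targets = config.target_residues
    if targets is None:
        linker_ids = [r.residue_id for r in model.residues if r.label == "linker"]
        targets = sorted(set(linker_ids + hinges[:3]))
    profiles = {}
    for t in targets:
        if t not in model:
            warnings.warn(f"target residue {t} not in structure; skipped")
            continue
        profiles[t] = {
            "influence": influence_profile(pmap, t),
            "response": response_profile(pmap, t),
        }
        _write_profile(
            outdir / f"influence_{t}.tsv",
            model.residue_ids,
            model.labels,
            profiles[t]["influence"],
        )
    bundle = {
        "model": model,
        "modes": modes,
        "mobility": profile,
        "hinges": hinges,
        "dynamics_fraction": frac,
        "n_modes_used": m,
        "prs_map": pmap,
        "effectors": effectors,
        "sensors": sensors,
        "effector_sensor_overlap": overlap,
        "target_profiles": profiles,
    }
    _write_manifest(
        config,
        outdir,
        "dynamics",
        {
            "hinges": hinges,
            "dynamics_fraction": frac,
            "effectors": effectors,
            "sensors": sensors,
        },
    )
    return bundle


def run_coevolution(config: RunConfig) -> dict:
    """Alignment → five scorers → consensus pairs + propensity profiles.

    Individual scorer failures are recorded and tolerated as long as at
    least two methods succeed (the consensus needs two independent
    witnesses); fewer than two aborts the stage.
    """
    if len(config.methods) < 2:
        raise ValueError(
            "coevolution consensus requires at least 2 methods; "
            f"configured: {config.methods}"
        )
    if not config.msa_path or not Path(config.msa_path).exists():
        raise FileNotFoundError(
            f"alignment file not found: {config.msa_path!r} (coevolution stage)"
        )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    msa = read_msa(config.msa_path, config.msa_format)
    if config.reference_id:
        msa = map_to_reference(msa, config.reference_id, config.reference_start)
    msa = filter_columns(msa, config.max_gap_fraction, mapped_only=bool(config.reference_id))
    msa = sequence_weights(msa, config.identity_threshold)
    entropy = shannon_entropy(msa)

    results: dict[str, CoevolutionResult] = {}
    failures: dict[str, str] = {}
    for name in config.methods:
        try:
            results[name] = run_method(name, msa)
        except Exception as err:  # noqa: BLE001 — failures are reported, not hidden
            failures[name] = f"{type(err).__name__}: {err}"
            warnings.warn(f"scorer {name} failed: {err}")
    if len(results) < 2:
        raise RuntimeError(
            f"only {len(results)} scorer(s) succeeded ({sorted(results)}); "
            f"failures: {failures}; consensus needs at least 2"
        )
    subs = {
        name: interdomain_submatrix(res, config.group_a, config.group_b)
        for name, res in results.items()
    }
    for name, sub in subs.items():
        np.savetxt(outdir / f"scores_{name}.tsv", np.nan_to_num(sub.matrix), delimiter="\t")
        with open(outdir / f"scores_{name}.json", "w") as fh:
            json.dump(results[name].params, fh, indent=2, default=str)
    table = consensus_pairs(
        list(results.values()),
        config.group_a,
        config.group_b,
        config.top_fraction,
        config.min_methods,
        config.k_override,
    )
    propensities = {
        name: {
            "A": cumulative_propensity(sub, "rows"),
            "B": cumulative_propensity(sub, "cols"),
        }
        for name, sub in subs.items()
    }
    write_consensus_table(table, outdir / "consensus_pairs.tsv")
    bundle = {
        "msa": msa,
        "entropy": entropy,
        "results": results,
        "failures": failures,
        "submatrices": subs,
        "consensus": table,
        "propensities": propensities,
    }
    _write_manifest(
        config,
        outdir,
        "coevolution",
        {
            "m_eff": msa.m_eff,
            "n_sequences": msa.n_sequences,
            "n_columns": msa.n_columns,
            "methods_succeeded": sorted(results),
            "methods_failed": failures,
            "n_consensus_pairs": len(table),
        },
    )
    return bundle


def run_all(config: RunConfig) -> dict:
    """Full pipeline plus the per-residue evidence cross-reference.

    For every detected hinge and every consensus pair member, the joint
    report lists PRS effectiveness and sensitivity and the conservation
    entropy of the mapped alignment column — the per-residue evidence
    summary combining dynamics and sequence signals.
    """
    dyn = run_dynamics(config)
    coev = run_coevolution(config)
    model = dyn["model"]
    pmap = dyn["prs_map"]
    table = coev["consensus"]
    if table.pairs:
        table = annotate_contacts(table, model)
        coev["consensus"] = table
        write_consensus_table(table, Path(config.output_dir) / "consensus_pairs.tsv")

    entropy_by_residue = {
        int(rid): float(h)
        for rid, h in zip(coev["msa"].column_map, coev["entropy"])
        if rid >= 0
    }
    residues_of_interest = sorted(
        set(dyn["hinges"])
        | {p.residue_a for p in table.pairs}
        | {p.residue_b for p in table.pairs}
    )
    evidence = []
    for rid in residues_of_interest:
        row = {"residue_id": rid, "roles": []}
        if rid in dyn["hinges"]:
            row["roles"].append("hinge")
        if any(rid in (p.residue_a, p.residue_b) for p in table.pairs):
            row["roles"].append("consensus_pair_member")
        if rid in model:
            pos = model.index_of(rid)
            row["effectiveness"] = float(pmap.effectiveness[pos])
            row["sensitivity"] = float(pmap.sensitivity[pos])
            row["domain"] = model.labels[pos]
        row["entropy"] = entropy_by_residue.get(rid)
        evidence.append(row)
    outdir = Path(config.output_dir)
    with open(outdir / "evidence_summary.json", "w") as fh:
        json.dump(evidence, fh, indent=2)
    _write_manifest(
        config,
        outdir,
        "all",
        {"n_evidence_rows": len(evidence)},
    )
    return {"dynamics": dyn, "coevolution": coev, "evidence": evidence}
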