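"""End-to-end orchestration with a single config, fixed seeds, and a manifest.

A pipeline run executes any subset of four stages — sequence conservation,
structure dynamics, single-molecule motility, saturation kinetics — each on
synthetic inputs generated from the run's seed (or on user-supplied files
for the structure stage). Every parameter that affects results is recorded
in the emitted run manifest together with output checksums, so re-running
an identical config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, seqcons, structdyn
from .sm import (
    classify_phenotype,
    displacement_stats,
    fit_saturation,
    straighten_track,
)
from .sm.tracking import Track
from .synth import (
    IndelSpec,
    KineticTruth,
    family_alignment,
    generate_sequence_family,
    generate_structure_pair,
    rotation_about,
    simulate_kinetics,
    simulate_tracks,
    translation_only,
)

__all__ = ["RunManifest", "validate_config", "run_pipeline", "build_report",
           "DEFAULT_CONFIG"]

STAGES = ("seq", "struct", "sm", "kinetics")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "stalk_run",
    "stages": list(STAGES),
    "seq": {
        "n_sequences": 200,
        "reference_length": 240,
        "cc1_span": [1, 110],
        "cc2_span": [131, 240],
        "substitution_rate": 0.05,
        "indel_fraction": 0.01,
        "indel_length": 2,
        "indel_position": 50,
    },
    "struct": {
        "paths": None,               # [state_a, state_b] to analyze real files
        "scheme": "yeast_dyn1",
        "align_on": "AAA1L",
        "rotate_subdomain": "AAA2L",
        "rotation_deg": 20.0,
        "translate_subdomain": "AAA5s",
        "translation_A": 8.0,
        "atoms_per_subdomain": 25,
    },
    "sm": {
        "n_per_mode": 30,
        "duration_s": 60.0,
        "frame_interval_s": 1.0,
        "v_nm_s": 100.0,
        "D_nm2_s": 10000.0,
        "k_off_s": 0.5,
        "loc_noise_nm": 20.0,
    },
    "kinetics": {
        "kcat": 15.18,
        "km_uM": 0.50,
        "kbasal": 0.75,
        "x_grid_uM": [0.0, 0.25, 0.5, 1.0, 2.0, 5.0],
        "noise_sd": 0.2,
        "replicates": 3,
    },
}


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    stages_run: list
    checksums: dict = field(default_factory=dict)   # relative path -> sha256
    warnings: list = field(default_factory=list)

    def to_json(self):
        return json.dumps(vars(self), indent=2, sort_keys=True)


def _canonical_hash(config):
    # The output location does not alter results; keep it out of the hash.
    payload = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def _merge(defaults, override):
    out = dict(defaults)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(config):
    """Merge onto defaults and reject unknown keys, listing all violations."""
    errors = []
    known_top = set(DEFAULT_CONFIG)
    for key in config:
        if key not in known_top:
            errors.append(f"unknown top-level key: {key}")
    for stage in STAGES:
        block = config.get(stage, {})
        if not isinstance(block, dict):
            errors.append(f"stage block {stage} must be a mapping")
            continue
        for key in block:
            if key not in DEFAULT_CONFIG[stage]:
                errors.append(f"unknown key {stage}.{key}")
    stages = config.get("stages", list(STAGES))
    for s in stages:
        if s not in STAGES:
            errors.append(f"unknown stage: {s}")
    if errors:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))
    return _merge(DEFAULT_CONFIG, config)


def _write(outdir, name, payload, checksums):
    path = Path(outdir) / name
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(payload, str):
        path.write_text(payload)
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
    checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stages

def _stage_seq(cfg, seed, outdir, checksums):
    rng = np.random.default_rng(seed)
    L = cfg["reference_length"]
    reference = "".join(
        "ACDEFGHIKLMNPQRSTVWY"[i] for i in rng.integers(0, 20, size=L)
    )
    spans = {"CC1": tuple(cfg["cc1_span"]), "CC2": tuple(cfg["cc2_span"])}
    family = generate_sequence_family(
        reference, n=cfg["n_sequences"],
        substitution_rate=cfg["substitution_rate"],
        indel_spec=[IndelSpec(cfg["indel_position"], cfg["indel_length"],
                              "deletion", cfg["indel_fraction"])],
        domain_spans=spans, seed=seed,
    )
    aln = family_alignment(family)
    anns = [
        seqcons.delineate_domain(aln, "reference", name, *span)
        for name, span in spans.items()
    ]
    dist = seqcons.domain_length_distribution(aln, anns, domain_name="stalk")
    profile = seqcons.conservation_profile(aln)
    mean_score = float(np.mean([
        c.amas_score for c in profile.columns if c.amas_score is not None
    ]))
    _write(outdir, "seq/stalk_lengths.json", dist.summary(), checksums)
    _write(outdir, "seq/conservation_summary.json", {
        "n_columns": len(profile.columns),
        "mean_amas_score": mean_score,
        "identity_fraction": float(np.mean([c.identity for c in profile.columns])),
    }, checksums)
    return {"modal_fraction": dist.modal_fraction, "mean_amas_score": mean_score}


def _stage_struct(cfg, seed, outdir, checksums, warnings):
    if cfg["paths"]:
        a = structdyn.load_structure(cfg["paths"][0])
        b = structdyn.load_structure(cfg["paths"][1])
        scheme = structdyn.load_subdomain_scheme(cfg["scheme"])
        defs = scheme["subdomains"]
        triple = scheme["triples"]["AAA2L_axis"]
        triple_a = triple_b = triple
    else:
        base = generate_structure_pair(
            atoms_per_subdomain=cfg["atoms_per_subdomain"], seed=seed)
        rot_name = cfg["rotate_subdomain"]
        res_lo, res_hi = base.subdomain_defs[rot_name][0]
        mid = (res_lo + res_hi) // 2
        triple_a = triple_b = (res_lo, mid, res_hi)
        pts = np.array([base.state_a.ca_coord(r) for r in triple_a])
        _, u = structdyn.principal_axis(pts)
        w = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(w) < 1e-6:
            w = np.cross(u, [0.0, 1.0, 0.0])
        w /= np.linalg.norm(w)
        res, _, xyz = base.state_a.ca_table()
        centroid = xyz[(res >= res_lo) & (res <= res_hi)].mean(axis=0)
        transforms = {
            rot_name: rotation_about(w, cfg["rotation_deg"], centroid),
            cfg["translate_subdomain"]: translation_only(
                [cfg["translation_A"], 0.0, 0.0]),
        }
        pair = generate_structure_pair(
            atoms_per_subdomain=cfg["atoms_per_subdomain"],
            transforms=transforms, seed=seed)
        a, b, defs = pair.state_a, pair.state_b, pair.subdomain_defs

    align_on = cfg["align_on"]
    fld = structdyn.displacement_field(a, b, align_on=align_on, definitions=defs)
    rot = structdyn.rotation_angle(a, b, triple_a, triple_b,
                                   align_on=align_on, definitions=defs)
    gap = structdyn.interface_gap(a, defs, "AAA5L", "AAA5s")
    _write(outdir, "struct/motion_summary.json", {
        "align_on": align_on,
        "rotation_angle_deg": rot.angle_deg,
        "superposition_rmsd_A": fld.superposition.rmsd,
        "subdomain_mean_max_displacement_A": fld.subdomain_summary,
        "AAA5_interface_gap_A": gap,
    }, checksums)
    return {"rotation_angle_deg": rot.angle_deg,
            "subdomain_summary": fld.subdomain_summary}


def _stage_sm(cfg, seed, outdir, checksums):
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]
    panel, calls = [], {}
    specs = [
        ("directional", {"v": cfg["v_nm_s"]}),
        ("diffusive", {"D": cfg["D_nm2_s"]}),
        ("static", {}),
        ("transient", {"k_off": cfg["k_off_s"],
                       "n_events": cfg["n_per_mode"]}),
    ]
    confusion = {}
    diffusive_straight = []
    for (mode, params), sd in zip(specs, seeds):
        ds = simulate_tracks(
            mode, params, duration=cfg["duration_s"],
            frame_interval=cfg["frame_interval_s"],
            n_tracks=cfg["n_per_mode"], loc_noise_sd=cfg["loc_noise_nm"],
            seed=sd,
        )
        for tr in ds.tracks:
            track = Track(track_id=tr.track_id,
                          frames=np.rint(tr.t / ds.frame_interval).astype(int),
                          t=tr.t, x=tr.x, y=tr.y)
            if track.t.size < 3:
                call_cat = "transient"   # too short to straighten: short dwell
            else:
                st = straighten_track(track)
                call_cat = classify_phenotype(st).category
                if mode == "diffusive":
                    diffusive_straight.append(st)
            confusion[(mode, call_cat)] = confusion.get((mode, call_cat), 0) + 1
            panel.append((mode, call_cat))
    accuracy = sum(1 for m, c in panel if m == c) / len(panel)
    stats = displacement_stats(diffusive_straight, interval=1.0)
    _write(outdir, "sm/phenotypes.json", {
        "accuracy": accuracy,
        "confusion": {f"{m}->{c}": n for (m, c), n in sorted(confusion.items())},
        "diffusive_mean_1s_displacement_nm": stats.mean,
        "diffusive_sd_1s_displacement_nm": stats.sd,
        "n_intervals": stats.n,
    }, checksums)
    return {"accuracy": accuracy, "mean_disp": stats.mean, "sd_disp": stats.sd}


def _stage_kinetics(cfg, seed, outdir, checksums):
    truth = KineticTruth(cfg["kcat"], cfg["km_uM"], cfg["kbasal"])
    ds = simulate_kinetics(truth, np.asarray(cfg["x_grid_uM"]),
                           noise_sd=cfg["noise_sd"],
                           replicates=cfg["replicates"], seed=seed)
    fit = fit_saturation(ds.x, ds.y, role="atpase")
    payload = {
        "truth": vars(truth),
        "fit": {k: getattr(fit, k) for k in
                ("amplitude", "K", "basal", "se_amplitude", "se_K",
                 "se_basal", "rss", "n", "identifiable")},
    }
    _write(outdir, "kinetics/atpase_fit.json", payload, checksums)
    return payload["fit"]


def run_pipeline(config=None, outdir=None):
    """Validate, run the selected stages in order, and emit a manifest.

    A failed stage aborts downstream stages but preserves completed outputs;
    the manifest records which stages ran and the checksum of every file
    written.
    """
    config = validate_config(dict(config or {}))
    if outdir is not None:
        config["outdir"] = str(outdir)
    out = Path(config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    stage_seeds = {
        s: int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2 ** 31))
        for i, s in enumerate(STAGES)
    }
    manifest = RunManifest(
        version=__version__, config_hash=_canonical_hash(config),
        seed=seed, stages_run=[],
    )
    results = {}
    for stage in STAGES:
        if stage not in config["stages"]:
            continue
        try:
            if stage == "seq":
                results["seq"] = _stage_seq(config["seq"], stage_seeds["seq"],
                                            out, manifest.checksums)
            elif stage == "struct":
                results["struct"] = _stage_struct(
                    config["struct"], stage_seeds["struct"], out,
                    manifest.checksums, manifest.warnings)
            elif stage == "sm":
                results["sm"] = _stage_sm(config["sm"], stage_seeds["sm"],
                                          out, manifest.checksums)
            elif stage == "kinetics":
                results["kinetics"] = _stage_kinetics(
                    config["kinetics"], stage_seeds["kinetics"], out,
                    manifest.checksums)
            manifest.stages_run.append(stage)
        except Exception as exc:  # abort downstream, keep completed outputs
            manifest.warnings.append(f"stage {stage} failed: {exc}")
            break
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest, results


def build_report(manifest, results, outdir=None):
    """Human-readable run summary; absent stages are marked, not fabricated."""
    lines = [
        "# dynstalk pipeline report",
        "",
        f"package version: {manifest.version}",
        f"config hash: {manifest.config_hash}",
        f"seed: {manifest.seed}",
        "",
    ]
    if not manifest.stages_run:
        lines.append("WARNING: no stages completed.")
    sections = {
        "seq": "## Sequence conservation",
        "struct": "## Structure dynamics",
        "sm": "## Single-molecule motility",
        "kinetics": "## Saturation kinetics",
    }
    for stage, header in sections.items():
        lines.append(header)
        if stage not in results:
            lines.append("(stage absent from this run)")
        else:
            for k, v in results[stage].items():
                lines.append(f"- {k}: {v}")
        lines.append("")
    if manifest.warnings:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in manifest.warnings)
        lines.append("")
    text = "\n".join(lines)
    if outdir is not None:
        Path(outdir, "report.md").write_text(text)
    return text
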