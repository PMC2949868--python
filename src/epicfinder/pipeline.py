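"""End-to-end orchestration: filter families, map introns, score
conservation, design primers, and write per-family reports plus a run
manifest.  Failures are recorded per family and do not stop the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from epicfinder import model
from epicfinder.conservation import compute_profile, export_plot_data
from epicfinder.filtering import evaluate_family, infer_duplications
from epicfinder.introns import cluster_introns, map_introns, select_candidate_introns
from epicfinder.primers import (
    NoPrimerError,
    PrimerParams,
    design_codehop,
    enumerate_pairs,
    extend_into_intron,
    predict_exon_amplicon,
)

log = logging.getLogger("epicfinder")


@dataclass
class PipelineConfig:
    e_max: float = 1e-5
    similarity_min: float = 0.5
    mode: str = "relaxed"
    tolerance: int = 6
    w: int = 20
    peak_w: int = 51
    min_presence: float = 0.5
    require_flanking_peaks: bool = False
    max_peak_distance: int = 120
    degeneracy_cap: int = 32
    preferred_cap: int = 8
    clamp_length: int = 12
    min_intron: int = 70
    ref_priority: List[str] = field(
        default_factory=lambda: ["Strongylocentrotus", "Ciona"]
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "e_max", "similarity_min", "tolerance", "w", "peak_w",
            "degeneracy_cap", "preferred_cap", "clamp_length", "min_intron",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")

    def primer_params(self) -> PrimerParams:
        return PrimerParams(
            clamp_length=self.clamp_length,
            cap=self.degeneracy_cap,
            preferred_cap=self.preferred_cap,
        )

    def to_yaml(self, path: Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def run_pipeline(
    config: PipelineConfig, bundle_dirs: List[Path], out_dir: Path
) -> Dict[str, object]:
    """Process each bundle directory; returns (and writes) the run manifest."""
    if not bundle_dirs:
        raise ValueError("no bundle directories supplied")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest: Dict[str, object] = {
        "config": dataclasses.asdict(config),
        "families": {},
    }
    n_failed = 0
    for bdir in bundle_dirs:
        fam = Path(bdir).name
        entry: Dict[str, object] = {}
        try:
            entry = _run_family(config, Path(bdir), out_dir / fam)
        except Exception as exc:  # partial-failure tolerant by design
            log.warning("family %s failed: %s", fam, exc)
            entry = {"status": "error", "error": str(exc)}
            n_failed += 1
        manifest["families"][fam] = entry
    manifest["n_failed"] = n_failed
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if n_failed == len(bundle_dirs):
        raise RuntimeError("all families failed; see manifest")
    return manifest


def _run_family(config: PipelineConfig, bundle_dir: Path, fam_out: Path) -> Dict[str, object]:
    bundle = model.read_family_bundle(bundle_dir)
    report = model.validate_translation(bundle)
    if not report.ok:
        return {"status": "rejected", "reason": "translation mismatches"}
    infer_duplications(bundle.tree, bundle.taxonomy)
    verdict = evaluate_family(bundle.tree, bundle.taxonomy, bundle.family_id)
    if not verdict.retained:
        return {"status": "rejected", "reason": "; ".join(verdict.reasons)}

    fam_out.mkdir(parents=True, exist_ok=True)
    codon = model.thread_codon_alignment(bundle)
    sites = map_introns(bundle, codon)
    clusters = cluster_introns(
        sites,
        mode=config.mode,
        tolerance=config.tolerance,
        taxonomy=bundle.taxonomy,
    )
    core_rows = [r.residues for r in codon.records]
    profile = compute_profile(core_rows, w=config.w, peak_w=config.peak_w)
    export_plot_data(profile, clusters).to_csv(
        fam_out / "profile.tsv", sep="\t", index=False
    )
    candidates = select_candidate_introns(
        clusters,
        min_presence=config.min_presence,
        require_flanking_peaks=config.require_flanking_peaks,
        profile=profile,
        max_peak_distance=config.max_peak_distance,
    )

    primer_rows = []
    params = config.primer_params()
    for cl, flank_omega, presence in candidates:
        try:
            fwd = design_codehop(
                bundle.proteins, codon, cl, "5'", config.ref_priority, params
            )
            rev = design_codehop(
                bundle.proteins, codon, cl, "3'", config.ref_priority, params
            )
        except NoPrimerError as exc:
            primer_rows.append(
                {"cluster": cl.cluster_id, "column": cl.consensus_column,
                 "status": f"no primer ({exc})"}
            )
            continue
        if fwd.abuts_intron:
            fwd = extend_into_intron(fwd, cl)
        for pair in enumerate_pairs(F=fwd, R=rev):
            for gid in bundle.gene_ids:
                pair.amplicon_sizes[gid] = predict_exon_amplicon(
                    pair, bundle.cds[gid].ungapped, params
                )
            primer_rows.append(
                {
                    "cluster": cl.cluster_id,
                    "column": cl.consensus_column,
                    "phase": cl.phase,
                    "pair": pair.label,
                    "forward": pair.forward.sequence,
                    "forward_code": pair.forward.descriptor,
                    "reverse": pair.reverse.sequence,
                    "reverse_code": pair.reverse.descriptor,
                    "flank_omega": round(flank_omega, 4),
                    "presence": round(presence, 4),
                    "amplicons": ";".join(
                        f"{g}:{v if v is not None else 'NA'}"
                        for g, v in pair.amplicon_sizes.items()
                    ),
                    "status": "ok",
                }
            )

    import pandas as pd

    pd.DataFrame(
        [
            {
                "cluster": cl.cluster_id,
                "column": cl.consensus_column,
                "phase": cl.phase,
                "n_sites": len(cl.sites),
                "span": cl.span,
            }
            for cl in clusters
        ]
    ).to_csv(fam_out / "introns.tsv", sep="\t", index=False)
    pd.DataFrame(primer_rows).to_csv(fam_out / "primers.tsv", sep="\t", index=False)
    return {
        "status": "retained",
        "n_sites": len(sites),
        "n_clusters": len(clusters),
        "n_candidates": len(candidates),
        "n_primer_rows": len(primer_rows),
        "exemptions": [r for r in verdict.reasons if r.startswith("exemption")],
    }
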