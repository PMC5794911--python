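"""End-to-end orchestration: cohort -> distances -> filtration -> inference.

`run_pipeline` drives a full analysis from a :class:`topoconn.io.RunConfig`:
it loads (or simulates) a cohort, computes per-subject distance matrices,
barcodes, single-linkage matrices and barcode slopes, then the group-level
slope t test, the edge-wise SLM permutation test, and clinical
correlations of the significant edges in group 2.  Outputs are plain text
files stamped with the config hash and seed; identical (config, seed)
pairs produce identical files.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .filtration import (
    Barcode,
    BarcodeSlope,
    Dendrogram,
    SingleLinkageMatrix,
    barcode,
    barcode_slope,
    single_linkage,
)
from .inference import (
    ClinicalCorrelationResult,
    EdgePermutationResult,
    SlopeComparison,
    clinical_correlations,
    compare_barcode_slopes,
    slm_permutation_test,
)
from .io import (
    RunConfig,
    write_barcode,
    write_distance_matrix,
    write_slm,
)
from .network import DistanceMatrix, PowerMatrix, pearson_distance
from .synthetic import CohortDataset, CohortSpec, generate_cohort

__all__ = [
    "PipelineError",
    "SubjectTopology",
    "CohortAnalysis",
    "subject_topology",
    "analyze_cohort",
    "load_cohort_manifest",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


@dataclass(frozen=True)
class SubjectTopology:
    """All per-subject derived objects."""

    subject_id: str
    distance: DistanceMatrix
    barcode: Barcode
    dendrogram: Dendrogram
    slm: SingleLinkageMatrix
    slope: BarcodeSlope


@dataclass(frozen=True)
class CohortAnalysis:
    """Per-subject topologies plus the three group-level results."""

    subjects: tuple[SubjectTopology, ...]
    group_labels: tuple[str, ...]
    slope_comparison: SlopeComparison
    slm_test: EdgePermutationResult
    clinical: ClinicalCorrelationResult | None


def subject_topology(
    pm: PowerMatrix, slope_window: tuple[int, int]
) -> SubjectTopology:
    """Distance matrix, barcode, dendrogram, SLM and slope for one subject."""
    dm = pearson_distance(pm)
    bc = barcode(dm)
    dendro, slm = single_linkage(dm)
    slope = barcode_slope(bc, n_range=slope_window)
    return SubjectTopology(
        subject_id=pm.subject_id,
        distance=dm,
        barcode=bc,
        dendrogram=dendro,
        slm=slm,
        slope=slope,
    )


def analyze_cohort(
    dataset: CohortDataset,
    slope_window: tuple[int, int],
    n_permutations: int = 10_000,
    alpha_slm: float = 0.001,
    alpha_clinical: float = 0.05,
    family_size: int | None = None,
    clinical_covariates: tuple[str, ...] = (),
    seed: int | None = None,
) -> CohortAnalysis:
    """Run all analysis stages on an in-memory cohort.

    Clinical correlations are computed in group 2 (the patient-like
    group) over the permutation test's significant edges; if none are
    significant, the clinical stage is skipped (``clinical=None``).
    """
    topos = tuple(
        subject_topology(pm, slope_window) for pm in dataset.subjects
    )
    is_a = [g == "group1" for g in dataset.group_labels]
    slopes_a = [t.slope.slope for t, a in zip(topos, is_a) if a]
    slopes_b = [t.slope.slope for t, a in zip(topos, is_a) if not a]
    slope_cmp = compare_barcode_slopes(slopes_a, slopes_b)
    slms_a = [t.slm for t, a in zip(topos, is_a) if a]
    slms_b = [t.slm for t, a in zip(topos, is_a) if not a]
    slm_test = slm_permutation_test(
        slms_a,
        slms_b,
        n_permutations=n_permutations,
        alpha=alpha_slm,
        seed=seed,
    )
    clinical = None
    sig = slm_test.significant_edges()
    if len(sig):
        edges = [(int(r.roi_i), int(r.roi_j)) for r in sig.itertuples()]
        ids_b = [
            pm.subject_id
            for pm, a in zip(dataset.subjects, is_a)
            if not a
        ]
        cov = dataset.covariates.loc[ids_b]
        if clinical_covariates:
            cov = cov[list(clinical_covariates)]
        else:
            cov = cov.drop(columns=["effect_scalar"], errors="ignore")
        clinical = clinical_correlations(
            slms_b,
            edges,
            cov,
            alpha=alpha_clinical,
            family_size=family_size,
        )
    return CohortAnalysis(
        subjects=topos,
        group_labels=dataset.group_labels,
        slope_comparison=slope_cmp,
        slm_test=slm_test,
        clinical=clinical,
    )


def load_cohort_manifest(path: str | Path) -> CohortDataset:
    """Rebuild a CohortDataset from a manifest written by ``write_cohort``."""
    from .io import read_power_matrix

    path = Path(path)
    manifest = json.loads(path.read_text())
    labels, subjects, rows, ids = [], [], [], []
    for rec in manifest["subjects"]:
        pm = read_power_matrix(
            path.parent / rec["file"],
            subject_id=rec["subject_id"],
            band=rec.get("band", "theta"),
        )
        labels.append(rec["group"])
        subjects.append(pm)
        rows.append(rec.get("covariates", {}))
        ids.append(rec["subject_id"])
    covariates = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    return CohortDataset(
        group_labels=tuple(labels),
        subjects=tuple(subjects),
        covariates=covariates,
        provenance=manifest.get("provenance", {}),
    )


def _stage(name: str):
    """Context turning any stage exception into a stage-named PipelineError."""
    import contextlib

    @contextlib.contextmanager
    def ctx():
        logger.info("stage %s", name)
        try:
            yield
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    return ctx()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis a config describes; returns the output dir.

    Every output file name carries ``<config-hash>.s<seed>`` so runs are
    traceable; a ``summary.json`` records the config, seed, and the
    group-level results.
    """
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    tag = f"{config.config_hash()}.s{config.seed}"
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("load_cohort"):
        if config.input_manifest is not None:
            dataset = load_cohort_manifest(config.input_manifest)
        else:
            spec_map = dict(config.cohort_spec)
            spec_map.setdefault("seed", config.seed)
            dataset = generate_cohort(CohortSpec(**spec_map))

    with _stage("analyze"):
        analysis = analyze_cohort(
            dataset,
            slope_window=config.slope_window,
            n_permutations=config.n_permutations,
            alpha_slm=config.alpha_slm,
            alpha_clinical=config.alpha_clinical,
            family_size=config.family_size,
            clinical_covariates=config.clinical_covariates,
            seed=config.seed,
        )

    with _stage("write_outputs"):
        subj_dir = outdir / f"subjects.{tag}"
        subj_dir.mkdir(exist_ok=True)
        slope_rows = []
        for topo, g in zip(analysis.subjects, analysis.group_labels):
            sid = topo.subject_id
            write_distance_matrix(topo.distance, subj_dir / f"{sid}.distance.tsv")
            write_barcode(topo.barcode, subj_dir / f"{sid}.barcode.tsv")
            write_slm(topo.slm, subj_dir / f"{sid}.slm.tsv")
            (subj_dir / f"{sid}.dendrogram.nwk").write_text(
                topo.dendrogram.to_newick() + "\n"
            )
            slope_rows.append(
                {
                    "subject_id": sid,
                    "group": g,
                    "slope": topo.slope.slope,
                    "intercept": topo.slope.intercept,
                    "n_points_used": topo.slope.n_points_used,
                }
            )
        pd.DataFrame(slope_rows).to_csv(
            outdir / f"slopes.{tag}.tsv", sep="\t", index=False
        )
        analysis.slm_test.table.to_csv(
            outdir / f"slm_test.{tag}.tsv", sep="\t", index=False
        )
        sig = analysis.slm_test.significant_edges()
        sig.to_csv(outdir / f"slm_significant.{tag}.tsv", sep="\t", index=False)
        if analysis.clinical is not None:
            analysis.clinical.table.to_csv(
                outdir / f"clinical.{tag}.tsv", sep="\t", index=False
            )
        sc = analysis.slope_comparison
        cfg_dict = config.to_dict()
        # analysis settings only: the output location is not part of identity
        cfg_dict.pop("output_dir", None)
        cfg_dict.pop("log_level", None)
        summary = {
            "config": cfg_dict,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "slope_comparison": {
                "t_statistic": sc.t_statistic,
                "degrees_of_freedom": sc.degrees_of_freedom,
                "p_value": sc.p_value,
                "group_means": list(sc.group_means),
                "significant": sc.p_value < config.alpha_slope,
            },
            "slm_test": {
                "n_permutations": analysis.slm_test.n_permutations,
                "alpha": analysis.slm_test.alpha,
                "n_significant_edges": int(len(sig)),
                "group_sizes": list(analysis.slm_test.group_sizes),
            },
            "clinical": (
                None
                if analysis.clinical is None
                else {
                    "family_size": analysis.clinical.family_size,
                    "corrected_alpha": analysis.clinical.corrected_alpha,
                    "n_significant": int(
                        analysis.clinical.table["significant"].sum()
                    ),
                }
            ),
        }
        (outdir / f"summary.{tag}.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
    logger.info("pipeline complete: %s", outdir)
    return outdir
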