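"""End-to-end orchestration: simulate a cohort, run every analysis stage in
order (conjunction → core → segments → FC → subcortex → profiles), and emit
a JSON-serializable report with provenance and built-in invariant checks.

The report is a pure function of (config, seed): rerunning with the same
configuration reproduces it byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .areastats import (
    area_ttests,
    conjunction_extended_md,
    core_classification,
    hemisphere_average,
    split_half_profile_correlation,
    task_profiles,
)
from .containers import BetaTable, ValidationError
from .fcnet import (
    classical_mds,
    connection_group_stats,
    fisher_z_inv,
    group_average_fc,
    network_crosstab,
)
from .segments import composite_area, segment_conjunction_test, segment_profile
from .subcortex import (
    permutation_null,
    replication_metrics,
    structure_task_conjunction,
)
from .synthdata import (
    GeneratorConfig,
    generate_segment_betas,
    generate_subcortical,
    generate_task_betas,
    iter_rest_timeseries,
    make_default_config,
)

__all__ = ["RunConfig", "run_pipeline", "extended_md_pipeline"]


@dataclass
class RunConfig:
    """Thresholds and sizes for one pipeline run.

    The multiple-comparison constants live here in one place: 180 areas
    per contrast, the extended-set size for the core test, 30 connection
    comparisons, 19 subcortical structures.
    """

    alpha: float = 0.05
    m_areas: int = 180
    m_comparisons: int = 30
    n_structures: int = 19
    n_perm: int = 10_000
    percentile: float = 97.5
    seed: int = 0
    # Subjects entering the per-subject FC stage.  Group FC statistics
    # converge quickly across subjects; a few dozen keep the stage fast.
    n_fc_subjects: int = 24
    generator: GeneratorConfig = None
    mds_k: int = 2

    def __post_init__(self):
        if self.alpha <= 0 or self.m_areas <= 0 or self.n_structures <= 0:
            raise ValidationError("thresholds and correction counts must be positive")
        if self.generator is None:
            self.generator = make_default_config(seed=self.seed)

    def fingerprint(self) -> str:
        payload = {
            "alpha": self.alpha,
            "m_areas": self.m_areas,
            "m_comparisons": self.m_comparisons,
            "n_structures": self.n_structures,
            "n_perm": self.n_perm,
            "percentile": self.percentile,
            "seed": self.seed,
            "n_fc_subjects": self.n_fc_subjects,
            "mds_k": self.mds_k,
            "generator_seed": self.generator.seed,
            "n_subjects": self.generator.n_subjects,
            "effect_table_sha": hashlib.sha256(
                np.ascontiguousarray(self.generator.effect_table).tobytes()
            ).hexdigest()[:16],
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def extended_md_pipeline(
    b: BetaTable, alpha: float = 0.05, m: int = 180
):
    """Hemisphere-average, per-contrast t-tests, three-way conjunction.

    Returns (averaged table, per-contrast stats, extended-set partition).
    """
    avg = hemisphere_average(b) if b.hemispheres is not None else b
    stats = {c: area_ttests(avg, c, alpha=alpha, m=m) for c in avg.contrast_ids}
    return avg, stats, conjunction_extended_md(stats)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate the cohort and run all stages; return the JSON-ready report."""
    gen = config.generator
    truth = gen.ground_truth
    report: dict = {
        "provenance": {
            "package": "mdcore",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.fingerprint(),
            "n_subjects": gen.n_subjects,
            "corrections": {
                "areas": config.m_areas,
                "connection_comparisons": config.m_comparisons,
                "structures": config.n_structures,
            },
        }
    }

    # --- task conjunction and core classification -------------------------
    betas = generate_task_betas(gen)
    avg, stats, extended = extended_md_pipeline(
        betas, alpha=config.alpha, m=config.m_areas
    )
    partition = core_classification(avg, extended.extended_set, alpha=config.alpha)
    report["extended_md"] = {
        "areas": sorted(extended.extended_set),
        "n_areas": len(extended.extended_set),
    }
    report["core_md"] = {
        "full": sorted(partition.core_full_set),
        "partial": sorted(partition.core_partial_set),
        "penumbra": sorted(partition.penumbra_set),
        "n_core": len(partition.core_set),
    }

    # --- border segments --------------------------------------------------
    seg_table = generate_segment_betas(gen)
    profile = segment_profile(seg_table)
    flags = segment_conjunction_test(
        seg_table, alpha=config.alpha, m=config.m_areas
    )
    composite = composite_area(seg_table, flags) if flags.any() else None
    report["segments"] = {
        "labels": list(seg_table.segment_labels),
        "mean_profile": profile.mean(axis=1).round(6).tolist(),
        "significant": flags.tolist(),
        "n_significant_scef": int(
            sum(f for f, a in zip(flags, seg_table.segment_areas) if a == "SCEF")
        ),
        "composite_mean": None if composite is None else composite.mean(axis=0).round(6).tolist(),
    }

    # --- functional connectivity ------------------------------------------
    atlas = gen.atlas
    parcel_partition = atlas.parcel_partition(scef_as_penumbra=True)
    fcs = []
    from .fcnet import parcel_fc

    n_fc = min(config.n_fc_subjects, gen.n_subjects)
    for ts in iter_rest_timeseries(gen, n_subjects=n_fc):
        fcs.append(parcel_fc(ts))
    group_stats = connection_group_stats(fcs, parcel_partition, alpha=config.alpha)
    group_means = {
        hemi: {
            "-".join(g): round(float(np.nanmean(group_stats.mean_z[hemi][:, gi])), 6)
            for gi, g in enumerate(group_stats.group_names)
        }
        for hemi in group_stats.hemispheres
    }
    networks = {
        pid: atlas.networks[area]
        for pid, area in zip(atlas.parcel_ids, atlas.parcel_area_names)
    }
    crosstab = network_crosstab(parcel_partition, networks)
    gavg = group_average_fc(fcs)
    md_parcels = [
        p for p in gavg.parcel_ids if parcel_partition[p] in ("core", "penumbra")
    ]
    md_idx = np.array([gavg.parcel_ids.index(p) for p in md_parcels])
    sub_r = gavg.r[np.ix_(md_idx, md_idx)]
    dist = 1.0 - sub_r
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    mds = classical_mds(dist, k=config.mds_k)
    md_classes = np.array([parcel_partition[p] for p in md_parcels])
    emb = mds.distances()
    core_mask = md_classes == "core"
    cc = emb[np.ix_(core_mask, core_mask)]
    cp = emb[np.ix_(core_mask, ~core_mask)]
    report["fc"] = {
        "n_subjects": n_fc,
        "n_parcels": fcs[0].n_parcels,
        "n_groups": len(group_stats.group_names),
        "n_comparisons": len(group_stats.comparisons),
        "group_mean_z": group_means,
        "n_significant_comparisons": int(
            sum(c["significant"] for c in group_stats.comparisons)
        ),
        "network_crosstab": crosstab,
        "mds": {
            "eigenvalues_top5": mds.eigenvalues[:5].round(6).tolist(),
            "n_negative_eigenvalues": mds.n_negative,
            "mean_core_core_distance": round(
                float(cc[np.triu_indices_from(cc, k=1)].mean()), 6
            ),
            "mean_core_penumbra_distance": round(float(cp.mean()), 6),
        },
    }

    # --- subcortex ---------------------------------------------------------
    voxels = generate_subcortical(gen)
    task_flags = structure_task_conjunction(
        voxels, alpha=config.alpha, n_structures=config.n_structures
    )
    core_parcels = [
        p for p in atlas.parcel_ids if parcel_partition[p] == "core"
    ]
    voxel_map = permutation_null(
        voxels,
        core_parcels,
        n_perm=config.n_perm,
        percentile=config.percentile,
        seed=config.seed,
    )
    by_structure: dict = {}
    structures = np.array(voxels.structures)
    for s in dict.fromkeys(voxels.structures):
        sel = structures == s
        by_structure[s] = {
            "n_voxels": int(sel.sum()),
            "n_task_conjunction": int(task_flags[sel].sum()),
            "n_fc_significant": int(voxel_map.significant[sel].sum()),
        }
    report["subcortex"] = {"by_structure": by_structure}

    # --- task profiles and split-half replication ---------------------------
    md_set = sorted(extended.extended_set)
    if len(md_set) >= 3:
        prof = task_profiles(avg, md_set)
        rng = np.random.default_rng(config.seed)
        half = np.zeros(avg.n_subjects, dtype=bool)
        half[rng.permutation(avg.n_subjects)[: avg.n_subjects // 2]] = True
        corr = split_half_profile_correlation(avg, md_set, half)
        n_c = corr.shape[0]
        off = corr[~np.eye(n_c, dtype=bool)]
        report["task_profiles"] = {
            "areas": list(prof.area_ids),
            "sd_between_tasks_mean": round(float(prof.sd_between_tasks.mean()), 6),
            "split_half_correlation": corr.round(6).tolist(),
            "diag_mean": round(float(np.diag(corr).mean()), 6),
            "offdiag_mean": round(float(off.mean()), 6),
        }
    else:
        report["task_profiles"] = None

    # --- invariant checks ---------------------------------------------------
    checks = {
        "conjunction_subset_of_each_contrast": all(
            extended.extended_set
            <= {a for a, s in extended.stats[c].items() if s.significant_positive}
            for c in avg.contrast_ids
        ),
        "core_subset_of_extended": partition.core_set <= partition.extended_set,
        "fc_group_count_is_6": len(group_stats.group_names) == 6,
        "comparison_count_is_30": len(group_stats.comparisons) == config.m_comparisons,
    }
    if truth is not None:
        checks["extended_matches_truth"] = (
            extended.extended_set == truth.extended_set
        )
        checks["core_full_matches_truth"] = (
            partition.core_full_set == truth.core_full_set
        )
        checks["core_partial_matches_truth"] = (
            partition.core_partial_set == truth.core_partial_set
        )
        checks["segments_match_truth"] = bool(
            np.array_equal(flags, truth.segment_truth.all(axis=1))
        )
    report["checks"] = {k: bool(v) for k, v in checks.items()}
    report["all_checks_pass"] = bool(all(checks.values()))
    return report
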