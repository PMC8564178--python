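"""End-to-end orchestration: synthetic cohort -> CBF -> FCS -> coupling ->
group inference -> mediation.

``run_all`` streams subjects one at a time (raw BOLD/ASL are dropped after
each subject's maps are computed), so memory stays flat at any cohort size.
The analysis path consumes only raw inputs: CBF is re-quantified from the
ASL frames and FCS recomputed from the BOLD series through the full
preprocessing chain.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .asl import cbf_from_asl
from .connectivity import compute_fcs
from .coupling import subject_coupling
from .group_stats import (
    demographics_table,
    partial_correlation,
    regionwise_ancova,
)
from .mediation import bootstrap_indirect
from .preproc import framewise_displacement, motion_exclusion, preprocess
from .synthetic import CohortSpec, generate_atlas, generate_tables, iter_subject_data

log = logging.getLogger("neurocouple")

__all__ = ["run_all"]


def _regional_means(vol, atlas, mask) -> dict[int, float]:
    out = {}
    for rid in atlas.region_ids:
        rmask = (atlas.labels == rid) & mask & vol.mask
        out[int(rid)] = float(vol.data[rmask].mean()) if rmask.any() else np.nan
    return out


def run_all(
    spec: CohortSpec | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    n_perm: int = 1000,
    alpha: float = 0.01,
    fwhm_mm: float = 6.0,
    n_boot: int = 5000,
) -> dict:
    """Run the complete analysis on a freshly generated synthetic cohort.

    Returns a dict with the cohort table, per-subject measures, region-wise
    permutation-ANCOVA results per measure (``cbf``, ``fcs``,
    ``coupling``), demographics tests, WMH-cognition partial correlations,
    and mediation results.  When ``out_dir`` is given, every table is also
    written as TSV.
    """
    spec = spec or CohortSpec()
    ss = np.random.SeedSequence(seed)
    table_seed, data_seed, stats_seed, boot_seed = ss.spawn(4)

    atlas, mask = generate_atlas(spec)
    cohort = generate_tables(spec, table_seed)
    frame = cohort.to_frame()

    subject_rows = []
    cbf_regional, fcs_regional, coup_regional = [], [], []
    for data in iter_subject_data(spec, cohort, atlas, mask, data_seed):
        subj = data["subject"]
        bold = data["bold"]
        qc = motion_exclusion(bold.motion_params)
        fd = framewise_displacement(bold.motion_params)

        clean = preprocess(bold, data["nuisance"], n_discard=spec.n_discard)
        fcs = compute_fcs(clean, mask)
        cbf = cbf_from_asl(data["asl"])
        coup = subject_coupling(subj.id, cbf, fcs, atlas, mask, fwhm_mm=fwhm_mm)

        subject_rows.append(
            {
                "id": subj.id,
                "group": subj.group,
                "motion_pass": qc["passed"],
                "mean_fd": float(fd.mean()),
                "global_cbf": float(cbf.data[mask & cbf.mask].mean()),
                "global_fcs": float(fcs.data[mask & fcs.mask].mean()),
                "global_coupling": coup.global_r,
            }
        )
        cbf_regional.append(_regional_means(cbf, atlas, mask))
        fcs_regional.append(_regional_means(fcs, atlas, mask))
        coup_regional.append(coup.regional_r)

    measures = pd.DataFrame(subject_rows)
    ids = measures["id"]
    cbf_df = pd.DataFrame(cbf_regional, index=ids)
    fcs_df = pd.DataFrame(fcs_regional, index=ids)
    coup_df = pd.DataFrame(coup_regional, index=ids)

    groups = frame["group"].to_numpy()
    covar = np.column_stack(
        [frame["age"].to_numpy(float), (frame["sex"] == "M").to_numpy(float)]
    )
    stats_children = stats_seed.spawn(3)
    region_stats = {
        name: regionwise_ancova(
            df, groups, covar, n_perm=n_perm, alpha=alpha, seed=int(child.generate_state(1)[0] % 2**31)
        )
        for (name, df), child in zip(
            {"cbf": cbf_df, "fcs": fcs_df, "coupling": coup_df}.items(), stats_children
        )
    }

    frame_qc = frame.assign(mean_fd=measures["mean_fd"].to_numpy())
    demo = demographics_table(
        frame_qc,
        continuous_anova=("mean_fd",),
        continuous_kruskal=("age", "education_years"),
    )

    # WMH load vs cognition, adjusted for age, sex, education
    covar3 = np.column_stack([covar, frame["education_years"].to_numpy(float)])
    fazekas = frame["fazekas_total"].to_numpy(float)
    cog_cols = [c for c in frame.columns if c.startswith("z_")]
    corr_rows = []
    for col in cog_cols:
        r, p = partial_correlation(fazekas, frame[col].to_numpy(float), covar3)
        corr_rows.append({"domain": col[2:], "r": r, "p": p})
    cognition_corr = pd.DataFrame(corr_rows)

    # mediation: WMH load -> regional CBF -> cognition, for domains with a
    # significant load-cognition association and regions with altered CBF
    sig_regions = region_stats["cbf"].loc[
        region_stats["cbf"]["significant"], "region_id"
    ].tolist()
    sig_domains = cognition_corr.loc[cognition_corr["p"] < 0.05, "domain"].tolist()
    boot_children = boot_seed.spawn(max(1, len(sig_regions) * max(1, len(sig_domains))))
    med_rows = []
    k = 0
    for rid in sig_regions:
        for domain in sig_domains:
            res = bootstrap_indirect(
                fazekas,
                cbf_df[rid].to_numpy(float),
                frame[f"z_{domain}"].to_numpy(float),
                covar3,
                n_boot=n_boot,
                seed=int(boot_children[k].generate_state(1)[0] % 2**31),
            )
            k += 1
            med_rows.append(
                {
                    "region_id": rid,
                    "domain": domain,
                    "a": res.a,
                    "b": res.b,
                    "indirect": res.indirect,
                    "c_total": res.c_total,
                    "c_prime": res.c_prime,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "significant": res.significant,
                }
            )
    mediation = pd.DataFrame(med_rows)

    results = {
        "spec": spec,
        "atlas": atlas,
        "mask": mask,
        "cohort": frame,
        "subject_measures": measures,
        "regional_cbf": cbf_df,
        "regional_fcs": fcs_df,
        "regional_coupling": coup_df,
        "region_stats": region_stats,
        "demographics": demo,
        "cognition_correlations": cognition_corr,
        "mediation": mediation,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "cohort.tsv", sep="\t", index=False)
        measures.to_csv(out / "subject_measures.tsv", sep="\t", index=False)
        cbf_df.to_csv(out / "regional_cbf.tsv", sep="\t")
        fcs_df.to_csv(out / "regional_fcs.tsv", sep="\t")
        coup_df.to_csv(out / "regional_coupling.tsv", sep="\t")
        for name, df in region_stats.items():
            df.to_csv(out / f"regionstats_{name}.tsv", sep="\t", index=False)
        demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
        cognition_corr.to_csv(out / "cognition_correlations.tsv", sep="\t", index=False)
        mediation.to_csv(out / "mediation.tsv", sep="\t", index=False)

    log.info(
        "stage=run_all subjects=%d regions=%d significant_cbf=%d seed=%d",
        len(frame),
        atlas.region_ids.size,
        len(sig_regions),
        seed,
    )
    return results
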