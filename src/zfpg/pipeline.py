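"""End-to-end orchestration: filter -> diversity -> differentiation ->
outlier scan -> genome scans -> LD decay, from a single configuration.

The differentiation estimates use the MAF-filtered, LD-pruned locus set
with significant outliers removed; the outlier analysis itself runs on the
unpruned (MAF-filtered only) set so candidate regions are not thinned
away.  A single top-level seed fans out to fixed per-stage child seeds so
every stage is individually reproducible.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import diversity, differentiation, fdist, ld, scan, synthgen
from .popio import (
    GenotypeDataset,
    HaplotypeAlignment,
    filter_loci,
    ld_prune,
    read_alignment,
    read_genotypes,
    write_genotypes,
)

log = logging.getLogger(__name__)

# fixed per-stage seed offsets derived from the top-level seed
_STAGE_OFFSETS = {
    "simulate": 1,
    "prune": 2,
    "fdist_null": 3,
    "theta": 4,
    "dest": 5,
    "amova": 6,
    "calibrate": 7,
}


def stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class RunConfig:
    """Inputs and settings for a full run.

    Provide either real input paths (vcf/popmap[/fasta]) or a simulation
    config, not neither.
    """

    out_dir: str
    seed: int = 1
    vcf: str | None = None
    popmap: str | None = None
    groupmap: str | None = None
    fasta: str | None = None
    fasta_popmap: str | None = None
    sim: synthgen.SimConfig | None = None
    maf_min: float = 0.01
    ld_prune_r2: float = 0.5
    fdist_sims: int = 30_000
    fdist_p_cut: float = 0.01
    fdist_het_min: float = 0.2
    fdist_groups: int = 20
    fdist_demes: int = 100
    calibrate_probe_loci: int = 500
    target_fst: float | None = None
    bin_size: int = 20_000_000
    window: int = 10_000_000
    min_snps: int = 6
    decay_bin_width: int = 5_000_000
    n_perm: int = 1000
    chrom_lengths: dict[str, int] | None = None

    def __post_init__(self):
        if self.sim is None and (self.vcf is None or self.popmap is None):
            raise ValueError("need either a simulation config or vcf+popmap inputs")


def _write_tsv(df: pd.DataFrame, path: str, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_full(cfg: RunConfig) -> dict:
    """Run the whole analysis; returns a dict of result objects and writes
    a TSV report bundle plus a run log under cfg.out_dir."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {}
    meta = {"seed": cfg.seed, "package": "zfpg"}

    # --- inputs ----------------------------------------------------------
    try:
        if cfg.sim is not None:
            sim_cfg = cfg.sim
            if sim_cfg.seed != stage_seed(cfg.seed, "simulate"):
                from dataclasses import replace
                sim_cfg = replace(sim_cfg, seed=stage_seed(cfg.seed, "simulate"))
            ds, truth = synthgen.simulate_snp_dataset(sim_cfg)
            report["truth"] = truth
        else:
            ds = read_genotypes(cfg.vcf, cfg.popmap, cfg.groupmap)
    except Exception as err:
        raise RuntimeError(f"stage 'input' failed: {err}") from err

    aln: HaplotypeAlignment | None = None
    if cfg.fasta is not None:
        try:
            aln = read_alignment(cfg.fasta, cfg.fasta_popmap or cfg.popmap)
        except Exception as err:
            raise RuntimeError(f"stage 'mtdna-input' failed: {err}") from err

    # --- filtering -------------------------------------------------------
    try:
        ds_filt = filter_loci(ds, maf_min=cfg.maf_min)
        ds_pruned = ld_prune(
            ds_filt, r2_max=cfg.ld_prune_r2, seed=stage_seed(cfg.seed, "prune")
        )
    except Exception as err:
        raise RuntimeError(f"stage 'filter' failed: {err}") from err
    meta["n_loci_input"] = ds.n_loci
    meta["n_loci_maf_filtered"] = ds_filt.n_loci
    meta["n_loci_ld_pruned"] = ds_pruned.n_loci

    # --- diversity -------------------------------------------------------
    try:
        hs_rows = [
            {"population": p, "H_S": diversity.mean_expected_het(ds_filt, p)}
            for p in ds_filt.populations
        ]
        n_tests, n_sig, n_exp = diversity.hwe_summary(ds_filt)
        report["hs_table"] = pd.DataFrame(hs_rows)
        report["hwe"] = (n_tests, n_sig, n_exp)
        _write_tsv(report["hs_table"], os.path.join(cfg.out_dir, "diversity_snp.tsv"), meta)
    except Exception as err:
        raise RuntimeError(f"stage 'diversity' failed: {err}") from err

    if aln is not None:
        try:
            hap_rows = []
            for p in aln.populations:
                if len(aln.pop_sequences(p)) >= 2:
                    st = diversity.haplotype_stats(aln, p)
                    hap_rows.append(
                        {"population": p, "S": st.S, "h": st.h, "pi_pct": 100 * st.pi, "n": st.n}
                    )
            report["mtdna_table"] = pd.DataFrame(hap_rows)
            _write_tsv(
                report["mtdna_table"], os.path.join(cfg.out_dir, "diversity_mtdna.tsv"), meta
            )
        except Exception as err:
            raise RuntimeError(f"stage 'mtdna-diversity' failed: {err}") from err

    # --- outlier analysis (unpruned set) ---------------------------------
    try:
        fcfg, pop_order = fdist.layout_from_dataset(ds_filt)
        from dataclasses import replace
        fcfg = replace(
            fcfg,
            n_sims=cfg.fdist_sims,
            seed=stage_seed(cfg.seed, "fdist_null"),
            n_groups=max(cfg.fdist_groups, len({g for g, _, _ in fcfg.sample_layout}) ),
            demes_per_group=max(
                cfg.fdist_demes,
                1 + max(d for _, d, _ in fcfg.sample_layout),
            ),
        )
        target = cfg.target_fst
        if target is None:
            target = differentiation.multilocus_theta(
                ds_filt.genotypes, ds_filt.pop_labels()
            )
        M1, M2 = fdist.calibrate(fcfg, target, probe_loci=cfg.calibrate_probe_loci)
        fcfg = replace(fcfg, M1=M1, M2=M2)
        null = fdist.simulate_null(fcfg)
        theta_per_locus = differentiation.per_locus_theta(ds_filt)
        from .popio import pooled_maf
        maf = pooled_maf(ds_filt)
        het = 2 * maf * (1 - maf)
        observed = [
            (l.locus_id, theta_per_locus[j], het[j])
            for j, l in enumerate(ds_filt.loci)
        ]
        calls = fdist.classify_outliers(
            observed, null, p_cut=cfg.fdist_p_cut, het_min=cfg.fdist_het_min
        )
        report["outliers"] = calls
        odf = pd.DataFrame(
            {
                "locus": [c.locus_id for c in calls],
                "fst": [c.fst for c in calls],
                "het_scaled": [c.scaled_het for c in calls],
                "p_high": [c.p_high for c in calls],
                "p_low": [c.p_low for c in calls],
                "class": [c.classification for c in calls],
            }
        )
        _write_tsv(odf, os.path.join(cfg.out_dir, "outliers.tsv"), meta)
    except Exception as err:
        raise RuntimeError(f"stage 'fdist' failed: {err}") from err

    # --- differentiation on pruned, outlier-free set ---------------------
    try:
        out_ids = {c.locus_id for c in report["outliers"] if c.classification in ("high", "low")}
        keep = np.array([l.locus_id not in out_ids for l in ds_pruned.loci])
        ds_diff = ds_pruned.subset_loci(keep)
        meta["n_loci_differentiation"] = ds_diff.n_loci
        theta = differentiation.wc_theta_overall(
            ds_diff, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "theta")
        )
        dest = differentiation.jost_dest(
            ds_diff, n_perm=cfg.n_perm, seed=stage_seed(cfg.seed, "dest")
        )
        report["theta"] = theta
        report["dest"] = dest
        ddf = pd.DataFrame(
            [
                {"statistic": "theta", "estimate": theta.theta,
                 "ci_low": theta.ci_low, "ci_high": theta.ci_high, "p": None},
                {"statistic": "dest", "estimate": dest.overall,
                 "ci_low": dest.ci_low, "ci_high": dest.ci_high, "p": dest.p_value},
            ]
        )
        _write_tsv(ddf, os.path.join(cfg.out_dir, "differentiation.tsv"), meta)
    except Exception as err:
        raise RuntimeError(f"stage 'differentiation' failed: {err}") from err

    # --- genome scans ----------------------------------------------------
    try:
        chrom_lengths = cfg.chrom_lengths
        if chrom_lengths is None and cfg.sim is not None:
            chrom_lengths = {
                synthgen._chrom_name(i): int(L)
                for i, L in enumerate(cfg.sim.chrom_lengths)
            }
        calls = report["outliers"]
        high_ids = {c.locus_id for c in calls if c.classification == "high"}
        mask = [l.locus_id in high_ids for l in ds_filt.loci]
        if chrom_lengths is not None:
            bins = scan.bin_outliers(ds_filt.loci, mask, chrom_lengths, cfg.bin_size)
            scan.annotate_bins(bins)
            report["bins"] = bins
            bdf = pd.DataFrame(
                {
                    "chrom": [b.chrom for b in bins],
                    "start": [b.start for b in bins],
                    "end": [b.end for b in bins],
                    "n_outliers": [b.n_outliers for b in bins],
                    "poisson_p": [b.poisson_p for b in bins],
                }
            )
            _write_tsv(bdf, os.path.join(cfg.out_dir, "bins.tsv"), meta)
        if high_ids:
            try:
                hwin = scan.het_window_scan(
                    ds_filt, None, calls, window=cfg.window,
                    min_snps=cfg.min_snps, chrom_lengths=chrom_lengths,
                )
                report["het_windows"] = hwin
                lwin = scan.ld_window_scan(
                    ds_filt, None, calls, window=cfg.window,
                    min_snps=cfg.min_snps, chrom_lengths=chrom_lengths,
                )
                report["ld_windows"] = lwin
                wdf = pd.DataFrame(
                    {
                        "focal": [w.focal_locus for w in hwin],
                        "chrom": [w.chrom for w in hwin],
                        "start": [w.start for w in hwin],
                        "end": [w.end for w in hwin],
                        "n_snps": [w.n_snps for w in hwin],
                        "mean_het": [w.statistic for w in hwin],
                        "p": [w.empirical_p for w in hwin],
                        "significant": [w.significant for w in hwin],
                    }
                )
                _write_tsv(wdf, os.path.join(cfg.out_dir, "sweep_windows.tsv"), meta)
            except ValueError as err:
                log.warning("window scans skipped: %s", err)
    except Exception as err:
        raise RuntimeError(f"stage 'scan' failed: {err}") from err

    # --- LD decay --------------------------------------------------------
    try:
        pairs = ld.syntenic_pairs(ds_filt)
        if pairs:
            try:
                fit = ld.fit_decay(pairs, bin_width=cfg.decay_bin_width)
                report["decay_fit"] = fit
                fdf = pd.DataFrame(
                    {
                        "bin_mid_mb": fit.bin_mid_bp / 1e6,
                        "n_pairs": fit.n_pairs,
                        "mean_r2": fit.mean_r2,
                    }
                )
                dm = dict(meta)
                dm["fit_a"] = fit.a
                dm["fit_b"] = fit.b
                dm["half_length_bp"] = ld.half_length(fit)
                _write_tsv(fdf, os.path.join(cfg.out_dir, "ld_decay.tsv"), dm)
            except ValueError as err:
                log.warning("LD decay fit skipped: %s", err)
    except Exception as err:
        raise RuntimeError(f"stage 'lddecay' failed: {err}") from err

    with open(os.path.join(cfg.out_dir, "run_log.yaml"), "w") as fh:
        yaml.safe_dump({k: v for k, v in meta.items()}, fh)
    return report
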