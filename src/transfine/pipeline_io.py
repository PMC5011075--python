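"""File formats, configuration, and end-to-end pipeline orchestration.

Formats are plain text throughout:

* summary statistics — tab-separated, ``#``-prefixed header comments
  (version, seed, parameter hash) followed by a column header. The
  *native* dialect carries ``chrom pos effect_allele other_allele eaf
  beta se p n info software``; the *minimal* dialect accepts the common
  ``chrom pos effect_allele other_allele beta se p n`` subset.
* annotation tracks — BED (0-based, half-open), ≥ 3 columns.
* configuration — YAML mirroring :class:`PipelineConfig`.

``run_all`` drives the whole analysis: simulate → per-study association
(+ first-round genomic control) → trans-ethnic meta-analysis (+ second
round, Cochran's Q) → locus definition → conditional analysis → Bayesian
fine-mapping → annotation enrichment, writing every artifact plus a run
manifest; reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, enrichment, finemap, meta, synthetic

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "StudyConfig",
    "RunManifest",
    "NATIVE_COLUMNS",
    "MINIMAL_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "read_bed",
    "write_bed",
    "run_all",
]

VERSION = "0.1.0"

NATIVE_COLUMNS = [
    "chrom", "pos", "effect_allele", "other_allele", "eaf",
    "beta", "se", "p", "n", "info", "software",
]
MINIMAL_COLUMNS = ["chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p", "n"]

_NUMERIC = {"pos": int, "eaf": float, "beta": float, "se": float, "p": float,
            "n": float, "info": float}


@dataclass
class StudyConfig:
    ancestry: str
    n: int
    fst: float = 0.05
    ld_rho: float = 0.9
    apply_gc: bool = True
    software: str = "IMPUTE2"


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; the seed governs all randomness."""

    seed: int = 0
    studies: list[StudyConfig] = field(
        default_factory=lambda: [
            StudyConfig("AFR", 500, fst=0.15, ld_rho=0.80),
            StudyConfig("HIS", 500, fst=0.08, ld_rho=0.88),
            StudyConfig("EUR", 500, fst=0.05, ld_rho=0.92, software="MACH"),
            StudyConfig("EAS", 500, fst=0.11, ld_rho=0.90),
        ]
    )
    n_variants: int = 200
    causal_beta: float = -1.0
    # desk-scale noise: scaled down from the full-cohort value so power at the
    # causal variant is preserved at hundreds of individuals per study
    residual_sd: float = 4.0
    significance: float = 5e-8
    half_window: int = meta.DEFAULT_HALF_WINDOW
    coverage_fraction: float = 0.5
    finemap_level: float = 0.99
    prior_sd: float = 0.2
    partition_mode: str = "tree"
    n_tracks: int = 8
    enrichment_log_odds: float = 2.0
    background_coverage: float = 0.1
    battery_size: int | None = None
    out_dir: str = "transfine_run"

    def param_hash(self) -> str:
        params = asdict(self)
        params.pop("out_dir")  # where results go does not change what they are
        payload = json.dumps(params, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        studies = [StudyConfig(**s) for s in raw.pop("studies", [])]
        cfg = cls(**raw)
        if studies:
            cfg.studies = studies
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class RunManifest:
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    parameters: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def record(self, stage: str, paths: list[Path]) -> None:
        self.stages.append(stage)
        for p in paths:
            key = str(p)
            if key in self.outputs:
                raise ValueError(f"output {key} recorded twice")
            self.outputs[key] = hashlib.sha256(p.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        payload = {
            "stages": self.stages,
            "outputs": self.outputs,
            "parameters": self.parameters,
            "started": self.started,
            "finished": self.finished,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


# ---------------------------------------------------------------------------
# Summary-statistics TSV
# ---------------------------------------------------------------------------

def _header_lines(config: PipelineConfig | None, seed=None) -> list[str]:
    seed_val = seed if seed is not None else (config.seed if config else "NA")
    phash = config.param_hash() if config else "NA"
    return [
        f"# transfine v{VERSION}",
        f"# seed={seed_val} params={phash}",
    ]


def write_summary_stats(
    df: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None,
    seed=None,
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in _header_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_summary_stats(
    path: str | Path, dialect: str = "native", rejects_path: str | Path | None = None
) -> pd.DataFrame:
    """Read and validate a summary-statistics table.

    Rows violating the record invariants (SE > 0, p in (0,1], frequency in
    (0,1), n > 0, unparsable numbers) are dropped and written, with a
    reason column, to ``rejects_path`` (default: ``<path>.rejects.tsv``).
    A missing mandatory column raises.
    """
    path = Path(path)
    if dialect == "native":
        required = NATIVE_COLUMNS
    elif dialect == "minimal":
        required = MINIMAL_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")

    reasons = pd.Series("", index=df.index, dtype=object)
    for col in required:
        if col not in _NUMERIC:
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if col == "se":
            bad |= vals <= 0
        elif col == "p":
            bad |= (vals <= 0) | (vals > 1)
        elif col in ("eaf", "info"):
            bad |= (vals < 0) | (vals > 1) if col == "info" else (vals <= 0) | (vals >= 1)
        elif col in ("n", "pos"):
            bad |= vals <= 0
        reasons[bad & (reasons == "")] = f"invalid {col}"
        df[col] = vals
    ok = reasons == ""
    rejects = df.loc[~ok].assign(reason=reasons[~ok])
    if len(rejects):
        rpath = Path(rejects_path) if rejects_path else path.with_suffix(path.suffix + ".rejects.tsv")
        rejects.to_csv(rpath, sep="\t", index=False)
        logger.warning("read_summary_stats: rejected %d rows -> %s", len(rejects), rpath)
    out = df.loc[ok].reset_index(drop=True)
    out["pos"] = out["pos"].astype(np.int64)
    for col in required:
        if col in _NUMERIC and col != "pos":
            out[col] = out[col].astype(float)
    return out


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, merge: bool = False) -> pd.DataFrame:
    """Read a BED file (0-based half-open) into chrom/start/end, sorted.

    ``merge=True`` merges overlapping or bookended intervals per chromosome.
    """
    path = Path(path)
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end ({end}) <= start ({start})")
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start", "end"], kind="mergesort"
    ).reset_index(drop=True)
    if merge and len(df):
        merged = []
        for chrom, grp in df.groupby("chrom", sort=False):
            cur_s, cur_e = None, None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        df = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    return df


def write_bed(intervals, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def _study_summary(ds: synthetic.StudyDataset, truth: synthetic.RegionTruth) -> pd.DataFrame:
    res = association.linear_assoc(ds.dosages, ds.phenotype, ds.covariates)
    freqs = ds.dosages.mean(axis=0) / 2.0
    tab = pd.DataFrame(
        {
            "chrom": truth.chrom,
            "pos": truth.positions,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": np.clip(freqs, 1e-4, 1 - 1e-4),
            "beta": res["beta"],
            "se": res["se"],
            "p": res["p"],
            "n": float(len(ds.phenotype)),
            "info": ds.info_scores,
            "software": ds.software,
        }
    )
    # monomorphic or covariate-collinear dosages come back NaN; drop them
    return tab.dropna(subset=["beta", "se", "p"]).reset_index(drop=True)


def run_all(config: PipelineConfig) -> RunManifest:
    """Run the full pipeline at the configured scale; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(parameters=asdict(config), started=time.time())
    rng_seed = int(config.seed)

    def fail(stage: str, exc: Exception):
        manifest.finished = time.time()
        manifest.write(out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    # --- stage 1: simulate -------------------------------------------------
    stage = "simulate"
    try:
        ancestries = tuple(
            synthetic.AncestryModel(s.ancestry, s.fst, s.ld_rho, s.n) for s in config.studies
        )
        truth = synthetic.simulate_region_truth(
            config.n_variants,
            ancestries=ancestries,
            seed=rng_seed,
            causal_beta=config.causal_beta,
            residual_sd=config.residual_sd,
        )
        datasets = [
            synthetic.simulate_study(
                truth, anc, seed=rng_seed + 1000 + i, software=config.studies[i].software,
                study_id=f"{anc.label}_{i}",
            )
            for i, anc in enumerate(ancestries)
        ]
        tracks = synthetic.simulate_annotation_tracks(
            truth, config.n_tracks, config.enrichment_log_odds,
            config.background_coverage, seed=rng_seed + 5000,
        )
        truth_df = pd.DataFrame(
            {
                "chrom": truth.chrom,
                "pos": truth.positions,
                "ancestral_freq": truth.ancestral_freqs,
                "causal": [
                    int(i in truth.causal_indices()) for i in range(truth.n_variants)
                ],
                "causal_beta": [
                    truth.causal_beta if i in truth.causal_indices() else 0.0
                    for i in range(truth.n_variants)
                ],
            }
        )
        paths = []
        tpath = out / "truth.tsv"
        write_summary_stats(truth_df, tpath, config)
        paths.append(tpath)
        for k, track in enumerate(tracks):
            bpath = out / f"track_{k:02d}.bed"
            write_bed(track, bpath)
            paths.append(bpath)
        manifest.record(stage, paths)
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        fail(stage, exc)

    # --- stage 2: per-study association + GC round 1 -----------------------
    stage = "association"
    try:
        study_tables = []
        paths = []
        for i, ds in enumerate(datasets):
            tab = _study_summary(ds, truth)
            tab = association.qc_filter(tab)
            if config.studies[i].apply_gc:
                _, tab = association.genomic_control(tab)
            study_tables.append(tab)
            spath = out / f"assoc_{ds.study_id}.tsv"
            write_summary_stats(tab, spath, config)
            paths.append(spath)
        manifest.record(stage, paths)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- stage 3: meta-analysis + GC round 2 + Q ---------------------------
    stage = "meta"
    try:
        meta_df = meta.meta_analyze(study_tables)
        _, meta_df = association.genomic_control(meta_df)
        mpath = out / "meta.tsv"
        write_summary_stats(meta_df, mpath, config)
        manifest.record(stage, [mpath])
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- stage 4: locus definition -----------------------------------------
    stage = "loci"
    try:
        loci = meta.define_loci(meta_df, config.significance, config.half_window)
        lpath = out / "loci.tsv"
        ldf = pd.DataFrame(
            [(l.chrom, l.lead_pos, l.lead_p, l.start, l.end) for l in loci],
            columns=["chrom", "lead_pos", "lead_p", "start", "end"],
        )
        write_summary_stats(ldf, lpath, config)
        manifest.record(stage, [lpath])
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- stage 5: conditional analysis -------------------------------------
    stage = "conditional"
    try:
        paths = []
        for li, locus in enumerate(loci):
            lead_idx = int(np.flatnonzero(truth.positions == locus.lead_pos)[0])
            cond_tables = []
            for i, ds in enumerate(datasets):
                res = association.conditional_assoc(
                    ds.dosages, ds.phenotype, ds.covariates, ds.dosages[:, lead_idx]
                )
                tab = _study_summary(ds, truth).assign(
                    beta=res["beta"], se=res["se"], p=res["p"]
                )
                cond_tables.append(tab.dropna(subset=["beta", "se"]).reset_index(drop=True))
            cond_meta = meta.meta_analyze(cond_tables, orient_decreasing=False)
            cond_meta["distinct_signal"] = meta.distinct_signal_test(cond_meta)
            cpath = out / f"conditional_locus{li}.tsv"
            write_summary_stats(cond_meta, cpath, config)
            paths.append(cpath)
        manifest.record(stage, paths)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- stage 6: fine-mapping ---------------------------------------------
    stage = "finemap"
    try:
        paths = []
        posterior_frames = []
        cs_rows = []
        for li, locus in enumerate(loci):
            in_window = [
                t.loc[
                    (t["chrom"] == locus.chrom)
                    & (t["pos"] >= locus.start)
                    & (t["pos"] <= locus.end)
                ].reset_index(drop=True)
                for t in study_tables
            ]
            shared = set(in_window[0]["pos"])
            for t in in_window[1:]:
                shared &= set(t["pos"])
            in_window = [
                t.loc[t["pos"].isin(shared)].sort_values("pos").reset_index(drop=True)
                for t in in_window
            ]
            post, cs = finemap.finemap_locus(
                in_window,
                prior_sd=config.prior_sd,
                level=config.finemap_level,
                partition_mode=config.partition_mode,
            )
            post.insert(0, "locus", li)
            posterior_frames.append(post)
            cs_rows.append((li, cs.size, cs.span_bp, cs.cumulative))
            ppath = out / f"posteriors_locus{li}.tsv"
            write_summary_stats(post, ppath, config)
            paths.append(ppath)
        cs_df = pd.DataFrame(cs_rows, columns=["locus", "set_size", "span_bp", "cumulative"])
        cpath = out / "credible_sets.tsv"
        write_summary_stats(cs_df, cpath, config)
        paths.append(cpath)
        manifest.record(stage, paths)
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    # --- stage 7: enrichment -----------------------------------------------
    stage = "enrichment"
    try:
        rows = []
        if posterior_frames:
            post_all = pd.concat(posterior_frames, ignore_index=True)
            pos = post_all["pos"].to_numpy()
            locus_labels = post_all["locus"].to_numpy()
            for k, track in enumerate(tracks):
                x = enrichment.overlap_indicators(pos, track)
                name = f"track_{k:02d}"
                try:
                    est_l = enrichment.enrichment_logistic(
                        post_all["pi"].to_numpy(), x, locus_labels,
                        annotation_name=name, battery_size=config.battery_size,
                    )
                    est_h = enrichment.hierarchical_bf_enrichment(
                        post_all["log10_bf"].to_numpy(), x, locus_labels,
                        annotation_name=name,
                    )
                except ValueError as err:
                    logger.warning("enrichment: skipping %s (%s)", name, err)
                    continue
                for est in (est_l, est_h):
                    rows.append(
                        (est.annotation, est.model, est.effect, est.se,
                         est.ci_low, est.ci_high, est.p, est.significant)
                    )
        epath = out / "enrichment.tsv"
        edf = pd.DataFrame(
            rows,
            columns=["annotation", "model", "effect", "se", "ci_low", "ci_high", "p", "significant"],
        )
        write_summary_stats(edf, epath, config)
        manifest.record(stage, [epath])
    except Exception as exc:  # noqa: BLE001
        fail(stage, exc)

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    logger.info("run_all: %d stages complete -> %s", len(manifest.stages), out)
    return manifest
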