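"""File formats, configuration and pipeline orchestration.

Formats are plain text: a tab-separated effect panel (header
``snp_id effect_allele other_allele eaf beta se``), a dosage TSV (first
column individual id, remaining columns per-SNP effect-allele dosages
0/1/2/NA), a sample TSV (``individual_id z group stratum``), and read-only
VCF via pysam. Dosages read from VCF are aligned to the panel's effect
allele by exact allele-string match; REF/ALT orientation is handled,
strand flipping is refused.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .panel import GenotypeMatrix, SnpPanel

__all__ = [
    "PANEL_COLUMNS",
    "RunConfig",
    "bundled_panel",
    "read_panel",
    "write_panel",
    "read_dosages",
    "write_dosages",
    "read_samples",
    "write_samples",
    "read_keyvalue_config",
    "write_table",
    "run_pipeline",
]

PANEL_COLUMNS = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se"]


def bundled_panel() -> SnpPanel:
    """The synthetic 160-SNP effect panel shipped with the package.

    A stand-in for an undeposited real GWAS hit list: 160 SNPs whose
    centered score explains 10% of trait variance.
    """
    ref = importlib.resources.files("polytail.data").joinpath("panel_160.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_panel(path)


def read_panel(path: str | Path) -> SnpPanel:
    """Read and validate an effect-panel TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str})
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: panel is missing columns {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if not 0.0 < row.eaf < 1.0:
            raise ValueError(f"{path}:{i}: eaf must lie in (0, 1), got {row.eaf}")
        if not np.isfinite(row.beta) or not np.isfinite(row.se) or row.se < 0:
            raise ValueError(f"{path}:{i}: malformed beta/se")
    if df.snp_id.duplicated().any():
        dupes = sorted(df.snp_id[df.snp_id.duplicated()])
        raise ValueError(f"{path}: duplicate snp_ids {dupes}")
    return SnpPanel.from_frame(df[PANEL_COLUMNS])


def write_panel(panel: SnpPanel, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        panel.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_dosages(path: str | Path, panel: SnpPanel) -> GenotypeMatrix:
    """Read a dosage TSV or VCF, aligned to the panel's SNP order.

    Panel SNPs absent from the file are listed in a warning and returned
    as all-missing columns, keeping the matrix aligned to the panel.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf" or path.name.lower().endswith(".vcf.gz"):
        return _read_vcf_dosages(path, panel)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    n = df.shape[0]
    out = np.full((n, len(panel)), np.nan)
    absent = []
    for j, sid in enumerate(panel.snp_ids):
        if sid in df.columns:
            out[:, j] = pd.to_numeric(df[sid], errors="raise").to_numpy(float)
        else:
            absent.append(sid)
    if absent:
        warnings.warn(
            f"{len(absent)} panel SNPs absent from {path.name}: {absent[:5]}...",
            stacklevel=2,
        )
    return GenotypeMatrix(
        dosages=out, snp_ids=list(panel.snp_ids), sample_ids=[str(i) for i in df.index]
    )


def _read_vcf_dosages(path: Path, panel: SnpPanel) -> GenotypeMatrix:
    import pysam

    by_id = {e.snp_id: (j, e) for j, e in enumerate(panel.effects)}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        out = np.full((len(samples), len(panel)), np.nan)
        seen: set[str] = set()
        for rec in vcf:
            if rec.id not in by_id:
                continue
            j, eff = by_id[rec.id]
            ref, alts = rec.ref, rec.alts or ()
            if len(alts) != 1:
                raise ValueError(f"{rec.id}: only biallelic records are supported")
            alt = alts[0]
            if {ref, alt} != {eff.effect_allele, eff.other_allele}:
                raise ValueError(
                    f"{rec.id}: VCF alleles {ref}/{alt} do not match panel "
                    f"{eff.effect_allele}/{eff.other_allele}; strand flipping "
                    "is refused — fix the input"
                )
            effect_is_alt = alt == eff.effect_allele
            for i, sample in enumerate(samples):
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                alt_count = sum(1 for a in gt if a == 1)
                out[i, j] = alt_count if effect_is_alt else len(gt) - alt_count
            seen.add(rec.id)
    absent = [sid for sid in panel.snp_ids if sid not in seen]
    if absent:
        warnings.warn(
            f"{len(absent)} panel SNPs absent from {path.name}", stacklevel=3
        )
    return GenotypeMatrix(out, list(panel.snp_ids), samples)


def write_dosages(
    genotypes: GenotypeMatrix, path: str | Path, seed: int | None = None
) -> None:
    ids = genotypes.sample_ids or [f"ind{i + 1}" for i in range(genotypes.n_individuals)]
    df = pd.DataFrame(genotypes.dosages, index=ids, columns=genotypes.snp_ids)
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index_label="individual_id", na_rep="NA", float_format="%g")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"individual_id": str})
    required = {"individual_id", "z", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: sample table needs columns {sorted(required)}")
    if "stratum" not in df.columns:
        df["stratum"] = "all"
    return df


def write_samples(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    """Write an analysis output TSV with a provenance header."""
    write_samples(df, path, seed)


def _header(seed: int | None) -> str:
    line = f"# polytail {__version__}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def read_keyvalue_config(path: str | Path) -> dict[str, str]:
    """Parse a simple ``key = value`` text configuration file."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


@dataclass
class RunConfig:
    """Settings for an end-to-end demonstration run."""

    seed: int
    out_dir: Path
    n_replicates: int = 500
    panel_path: Path | None = None
    pool_size: int = 20_000
    cutoff: float = 2.326
    n_short: int = 120
    n_tall: int = 120
    missing_rate: float = 0.02
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        self.out_dir = Path(self.out_dir)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Simulate a cohort, score it, and test it against its own null.

    Runs simulate -> WAS -> per-SNP association -> mean-WAS tail test on a
    single synthetic cohort and writes TSV artifacts (all carrying the
    seed in their headers) to ``config.out_dir``. Returns the artifact
    paths.
    """
    import time

    from . import association as assoc_mod
    from .inference import null_mean_was_distribution, mean_was_pvalue, tall_short_was_ttest
    from .panel import compute_was
    from .simulate import (
        ThresholdScheme,
        apply_missingness,
        ascertain_threshold,
        simulate_genotypes,
        simulate_zscores,
    )

    cfg = config
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    panel = read_panel(cfg.panel_path) if cfg.panel_path else bundled_panel()
    scheme = ThresholdScheme(
        pool_size=cfg.pool_size,
        cutoff_short=-cfg.cutoff,
        cutoff_tall=cfg.cutoff,
        n_short=cfg.n_short,
        n_tall=cfg.n_tall,
    )
    paths: dict[str, Path] = {}

    def stage(name: str):
        t0 = time.perf_counter()

        def done() -> None:
            cfg.log.append(f"{name}: {time.perf_counter() - t0:.2f}s")

        return done

    done = stage("simulate")
    genotypes = simulate_genotypes(panel, scheme.pool_size, rng)
    z = simulate_zscores(genotypes, panel, None, rng)
    cohort = ascertain_threshold(genotypes, z, scheme, rng)
    cohort.dosages = apply_missingness(cohort.dosages, cfg.missing_rate, rng)
    done()

    done = stage("was")
    was = compute_was(cohort.dosages, panel)
    samples = pd.DataFrame(
        {
            "individual_id": cohort.dosages.sample_ids,
            "z": cohort.z,
            "group": cohort.group,
            "stratum": cohort.stratum,
            "was": was.score,
        }
    )
    paths["samples"] = cfg.out_dir / "samples.tsv"
    write_samples(samples, paths["samples"], cfg.seed)
    paths["dosages"] = cfg.out_dir / "dosages.tsv"
    write_dosages(cohort.dosages, paths["dosages"], cfg.seed)
    done()

    done = stage("assoc")
    rows = []
    case = (cohort.group == "tall").astype(int)
    for j, sid in enumerate(panel.snp_ids):
        try:
            tables = assoc_mod.allele_tables(
                cohort.dosages.dosages[:, j], cohort.group, cohort.stratum
            )
            res = assoc_mod.cmh_test(tables)
        except ValueError:
            continue
        lo, hi = res.ci95
        rows.append(
            {
                "snp_id": sid,
                "or_obs": res.or_observed,
                "ci_lo": lo,
                "ci_hi": hi,
                "p": res.p_value,
                "direction_consistent": res.direction == np.sign(panel.betas[j]),
            }
        )
    paths["assoc"] = cfg.out_dir / "assoc.tsv"
    write_table(pd.DataFrame(rows), paths["assoc"], cfg.seed)
    done()

    done = stage("tail-test")
    nulls = null_mean_was_distribution(
        panel, scheme, None, cfg.n_replicates, rng, missing_rates=cfg.missing_rate
    )
    t_stat, t_p = tall_short_was_ttest(
        was.score[cohort.group == "tall"], was.score[cohort.group == "short"]
    )
    summary = []
    for g, null in nulls.items():
        obs = float(np.nanmean(was.score[cohort.group == g]))
        summary.append(
            {
                "group": g,
                "observed_mean_was": obs,
                "mu_simulation": null.mu_simulation,
                "sigma2_simulation": null.sigma2_simulation,
                "p_value": mean_was_pvalue(obs, null),
                "tall_vs_short_t": t_stat,
                "tall_vs_short_p": t_p,
            }
        )
    paths["tail_test"] = cfg.out_dir / "tail_test.tsv"
    write_table(pd.DataFrame(summary), paths["tail_test"], cfg.seed)
    done()

    paths["log"] = cfg.out_dir / "run.log"
    paths["log"].write_text(
        _header(cfg.seed) + "\n".join(cfg.log) + "\n"
    )
    return paths
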