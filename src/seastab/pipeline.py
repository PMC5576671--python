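"""End-to-end analysis: survey -> metrics -> models -> report bundle.

``run_full_analysis`` composes the four analysis stages per age class
(total / juvenile / subadult / adult): univariate mixed-model tables,
PERMANOVA + SIMPER on site-level communities, nMDS trajectory-stability
metrics with their management comparison, piecewise SEM per management
level, and (for the whole community) the pairwise-slope synchrony
analysis.  Every intermediate table is written to disk, a manifest
records seeds, settings and checksums, and rerunning with the same
configuration is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import response_table
from .lmm import CommunityLMM, lrt_vs_null, nakagawa_r2
from .ordination import bray_curtis, nmds
from .permanova import permanova, simper
from .sem import PathModel, fit_psem
from .simulate import GeneratorConfig, generate_survey
from .stability import compare_stability, metrics_frame, stability_by_site
from .survey import (AgeClassRule, aggregate_density,
                     cover_table, read_species_table, read_survey_csv,
                     rule_from_species_table, validate_survey,
                     write_species_table, write_survey_csv)
from .synchrony import compare_mean_slopes, pairwise_slopes, shared_species

AGE_BRANCHES = ("total", "juvenile", "subadult", "adult")


@dataclass
class AnalysisConfig:
    """Everything one run needs; the seed is mandatory for every
    stochastic stage."""

    out_dir: str | Path
    seed: int
    generator: GeneratorConfig | None = None
    fish_csv: str | Path | None = None
    cover_csv: str | Path | None = None
    species_csv: str | Path | None = None
    n_perm: int = 999
    alpha: float = 0.05
    nmds_restarts: int = 20
    nmds_max_iter: int = 300
    nmds_tol: float = 1e-7
    age_classes: tuple[str, ...] = AGE_BRANCHES

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.generator is None and (self.fish_csv is None or
                                       self.cover_csv is None):
            raise ValueError("provide either a generator config or survey CSVs")

    def settings_dict(self) -> dict:
        d = {k: v for k, v in dataclasses.asdict(self).items()
             if k not in ("generator",)}
        d["out_dir"] = str(self.out_dir)
        for k in ("fish_csv", "cover_csv", "species_csv"):
            if d[k] is not None:
                d[k] = str(d[k])
        d["age_classes"] = list(self.age_classes)
        d["generator"] = (self.generator.to_dict()
                          if self.generator is not None else None)
        return d


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fanned out from the root seed."""
    mix = np.random.default_rng([int(root_seed) % 2**31,
                                 zlib.crc32(stage.encode())])
    return int(mix.integers(0, 2**31))


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"analysis stage {stage!r} failed: {err}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the whole pipeline and return the manifest (also written to
    ``manifest.json``).  Any stage failure aborts with the stage name
    after writing a partial manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "settings": config.settings_dict(),
        "seed": config.seed,
        "stage_seeds": {},
        "stages": [],
        "branches": {},
        "files": {},
        "notes": ["the only cross-stage significance dependency is the "
                  "Fisher's C acceptance rule inside the SEM stage"],
    }

    def record(stage: str) -> None:
        manifest["stages"].append(stage)

    def fail(stage: str, err: Exception):
        manifest["error"] = {"stage": stage, "message": str(err)}
        _write_manifest(out, manifest)
        raise StageError(stage, err) from err

    # -- stage: data -------------------------------------------------------
    stage = "data"
    try:
        if config.generator is not None:
            gen = config.generator.replace(seed=stage_seed(config.seed, "simulate"))
            manifest["stage_seeds"]["simulate"] = gen.seed
            records = generate_survey(gen)
            write_survey_csv(records, out / "fish.csv", out / "cover.csv")
            write_species_table(gen.species_table(), out / "species.csv")
            rule = AgeClassRule.from_lmax(
                dict(zip(gen.species, gen.lmax_cm)))
            design = gen.design
        else:
            records = read_survey_csv(config.fish_csv, config.cover_csv)
            design = None
            if config.species_csv is not None:
                rule = rule_from_species_table(
                    read_species_table(config.species_csv))
            else:
                rule = AgeClassRule(default=(10.0, 20.0))
        report = validate_survey(records, design)
        if not report.ok:
            raise ValueError(f"survey validation failed: {report.violations[:5]}")
        record(stage)
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001 - manifest must name the stage
        fail(stage, err)

    covers = cover_table(records, level="transect")
    cover_z = ((covers["cover_pct"] - covers["cover_pct"].mean())
               / covers["cover_pct"].std(ddof=1))

    for branch in config.age_classes:
        age_filter = None if branch == "total" else branch
        bdir = out / branch
        bdir.mkdir(exist_ok=True)
        branch_files: dict[str, str] = {}

        # -- densities -----------------------------------------------------
        stage = f"{branch}/aggregate"
        try:
            transects = aggregate_density(records, level="transect",
                                          age_filter=age_filter, rule=rule)
            site_sum = aggregate_density(records, level="site",
                                         aggregation="sum",
                                         age_filter=age_filter, rule=rule)
            record(stage)
        except Exception as err:  # noqa: BLE001
            fail(stage, err)

        # -- univariate mixed models --------------------------------------
        stage = f"{branch}/lmm"
        try:
            resp = response_table(transects, transform="sqrt", standardize=True)
            responses = (["density", "richness", "shannon"]
                         if branch == "total" else ["density"])
            table = _lmm_table(resp, responses, config.alpha)
            table.to_csv(bdir / "lmm_table.csv", index=False)
            branch_files["lmm_table"] = str(bdir / "lmm_table.csv")
            record(stage)
        except Exception as err:  # noqa: BLE001
            fail(stage, err)

        # -- PERMANOVA + SIMPER -------------------------------------------
        stage = f"{branch}/permanova"
        try:
            d_site = bray_curtis(site_sum)
            seed_p = stage_seed(config.seed, f"{branch}/permanova")
            manifest["stage_seeds"][stage] = seed_p
            perm = permanova(d_site, site_sum.sample_info,
                             terms=("season", "management",
                                    "season:management"),
                             strata="site", n_perm=config.n_perm, seed=seed_p)
            perm.table.to_csv(bdir / "permanova.csv")
            branch_files["permanova"] = str(bdir / "permanova.csv")
            seed_s = stage_seed(config.seed, f"{branch}/simper")
            manifest["stage_seeds"][f"{branch}/simper"] = seed_s
            simp = simper(site_sum, "management", n_perm=min(config.n_perm, 199),
                          seed=seed_s)
            simp.table.to_csv(bdir / "simper_management.csv", index=False)
            branch_files["simper"] = str(bdir / "simper_management.csv")
            record(stage)
        except Exception as err:  # noqa: BLE001
            fail(stage, err)

        # -- nMDS + stability ---------------------------------------------
        stage = f"{branch}/stability"
        try:
            seed_n = stage_seed(config.seed, f"{branch}/nmds")
            manifest["stage_seeds"][f"{branch}/nmds"] = seed_n
            ord_res = nmds(d_site, n_components=2,
                           n_restarts=config.nmds_restarts,
                           max_iter=config.nmds_max_iter,
                           tol=config.nmds_tol, seed=seed_n)
            ord_res.to_csv(bdir / "ordination.csv")
            (bdir / "ordination_meta.json").write_text(json.dumps(
                {"stress": ord_res.stress, "converged": bool(ord_res.converged),
                 "n_restarts": ord_res.n_restarts, "seed": seed_n}, indent=1))
            metrics = stability_by_site(ord_res.coords, site_sum.sample_info)
            metrics_frame(metrics).to_csv(bdir / "stability_metrics.csv",
                                          index=False)
            comp = compare_stability(metrics)
            comp.table.to_csv(bdir / "stability_comparison.csv")
            branch_files["ordination"] = str(bdir / "ordination.csv")
            branch_files["stability_metrics"] = str(bdir / "stability_metrics.csv")
            branch_files["stability_comparison"] = str(
                bdir / "stability_comparison.csv")
            record(stage)
        except Exception as err:  # noqa: BLE001
            fail(stage, err)

        # -- piecewise SEM per management ---------------------------------
        stage = f"{branch}/sem"
        try:
            sem_df = transects.sample_info.copy()
            sem_df["cover"] = cover_z.loc[sem_df.index]
            total = transects.values.sum(axis=1)
            sd = np.sqrt(total)
            sem_df["density"] = (sd - sd.mean()) / sd.std(ddof=1)
            path_model = PathModel.seagrass_mediation("density", direct=False)
            sems = {}
            for mgmt in ("MPA", "open"):
                res = fit_psem(path_model, sem_df, management_subset=mgmt)
                sems[mgmt] = res
                (bdir / f"sem_{mgmt}.json").write_text(
                    json.dumps(res.to_json_dict(), indent=1))
                branch_files[f"sem_{mgmt}"] = str(bdir / f"sem_{mgmt}.json")
            record(stage)
        except Exception as err:  # noqa: BLE001
            fail(stage, err)

        manifest["branches"][branch] = branch_files

    # -- synchrony (whole community) --------------------------------------
    stage = "synchrony"
    try:
        site_mean = aggregate_density(records, level="site", aggregation="mean")
        common = shared_species(site_mean)
        mpa_slopes = pairwise_slopes(site_mean, "MPA", species=common)
        open_slopes = pairwise_slopes(site_mean, "open", species=common)
        mpa_slopes.to_csv(out / "slopes_MPA.csv")
        open_slopes.to_csv(out / "slopes_open.csv")
        comp = compare_mean_slopes(mpa_slopes, open_slopes)
        (out / "synchrony_comparison.json").write_text(
            json.dumps(comp.to_json_dict(), indent=1))
        manifest["files"]["synchrony"] = [str(out / "slopes_MPA.csv"),
                                          str(out / "slopes_open.csv"),
                                          str(out / "synchrony_comparison.json")]
        record(stage)
    except Exception as err:  # noqa: BLE001
        fail(stage, err)

    # -- checksums + manifest ---------------------------------------------
    checksums = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(out))] = _sha256(path)
    manifest["checksums"] = checksums
    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))


def _lmm_table(resp: pd.DataFrame, responses: list[str], alpha: float
               ) -> pd.DataFrame:
    """Table-1-shaped summary: per response, per-term F tests, LRT against
    the random-effects-only null, R^2, and Tukey season contrasts when
    season matters (within management when the interaction does)."""
    rows = []
    for name in responses:
        try:
            model = CommunityLMM.from_dataframe(
                resp, name, fixed=("season", "management",
                                   "season:management"), group="site")
            fit = model.fit(reml=True)
        except ValueError as err:
            rows.append({"response": name, "term": "skipped", "note": str(err)})
            continue
        r2m, r2c = nakagawa_r2(fit)
        full_ml = model.fit(reml=False)
        null_ml = CommunityLMM.from_dataframe(resp, name, fixed=(),
                                              group="site").fit(reml=False)
        chi2, dflr, plr = lrt_vs_null(full_ml, null_ml)
        anova = fit.anova()
        for term, row in anova.iterrows():
            rows.append({"response": name, "term": term, "F": row["F"],
                         "DFnum": int(row["DFnum"]), "DFden": row["DFden"],
                         "P": row["P"], "R2m": r2m, "R2c": r2c,
                         "LRT_chi2": chi2, "LRT_df": dflr, "LRT_p": plr})
        inter_p = anova.loc["season:management", "P"]
        season_p = anova.loc["season", "P"]
        if inter_p < alpha:
            for mgmt in ("MPA", "open"):
                tk = fit.tukey("season", within={"management": mgmt})
                for _, r in tk.iterrows():
                    rows.append({"response": name,
                                 "term": f"tukey[{mgmt}] {r['contrast']}",
                                 "estimate": r["estimate"], "SE": r["se"],
                                 "P": r["p_adjusted"]})
        elif season_p < alpha:
            tk = fit.tukey("season")
            for _, r in tk.iterrows():
                rows.append({"response": name, "term": f"tukey {r['contrast']}",
                             "estimate": r["estimate"], "SE": r["se"],
                             "P": r["p_adjusted"]})
    return pd.DataFrame(rows)
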