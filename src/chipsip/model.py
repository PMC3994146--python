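"""Model/Results interface tying the pipeline stages together.

``TrophicResponseModel`` holds the data (probe-spot table, optional 16S
tree) and configuration; ``fit()`` runs delta conversion, per-taxon HCE
regressions, enrichment flags, activity ranking, ANCOVA guild
classification, ternary normalization and (when a tree is present) the
phylogenetic-signal tests, returning a ``TrophicResponseResults`` carrying
the estimates, their uncertainties and diagnostics.

Example
-------
>>> from chipsip import simulate, TrophicResponseModel
>>> table, tree, truth = simulate.simulate_dataset(n_taxa=20, rng_seed=1)
>>> res = TrophicResponseModel(table, tree=tree).fit(seed=1)
>>> print(res.summary())                              # doctest: +SKIP
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Mapping, Optional

import dendropy
import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import TREATMENTS, AnalysisConfig
from .errors import ChipSipError, DegenerateDesignError, InsufficientDataError
from .guilds import (GUILD_PATTERNS, GUILDS, GuildAssignment, assign_guild,
                     rank_activity)
from .io import RESULT_COLUMNS, read_probe_table, read_tree, write_results
from .isotope import HceEstimate, compute_delta, fit_taxon_hces
from .phylo import PhyloCharacter, plot_null_histogram, test_all_guilds
from .ternary import TernaryPoint, normalize_hce, render_ternary

logger = logging.getLogger("chipsip")


class TrophicResponseModel:
    """Trophic-strategy model for one Chip-SIP experiment.

    Parameters
    ----------
    probe_table
        Validated probe-spot table in internal layout (see
        :func:`chipsip.io.read_probe_table`); delta values are derived from
        ion counts where absent.
    tree
        Optional dendropy tree of the targeted OTUs; without it every stage
        except the phylogenetic-signal test still runs.
    config
        :class:`AnalysisConfig`; defaults apply when omitted.
    """

    def __init__(self, probe_table: pd.DataFrame,
                 tree: Optional[dendropy.Tree] = None,
                 config: Optional[AnalysisConfig] = None):
        self.config = config or AnalysisConfig()
        self.tree = tree
        self.data = self._prepare(probe_table)

    @classmethod
    def from_files(cls, probes_path: str, tree_path: Optional[str] = None,
                   config: Optional[AnalysisConfig] = None,
                   columns: Optional[Mapping[str, str]] = None,
                   sep: Optional[str] = None) -> "TrophicResponseModel":
        table = read_probe_table(probes_path, columns=columns, sep=sep)
        tree = read_tree(tree_path) if tree_path else None
        return cls(table, tree=tree, config=config)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       tree: Optional[dendropy.Tree] = None,
                       config: Optional[AnalysisConfig] = None
                       ) -> "TrophicResponseModel":
        """Build a model from an unvalidated DataFrame in internal layout."""
        from .io import validate_probe_table
        for col in ("delta_permil", "count_14N", "count_15N"):
            if col not in df.columns:
                df = df.assign(**{col: pd.NA})
        return cls(validate_probe_table(df), tree=tree, config=config)

    def _prepare(self, table: pd.DataFrame) -> pd.DataFrame:
        df = table.copy()
        need_delta = df["delta_permil"].isna()
        if need_delta.any():
            c15 = df.loc[need_delta, "count_15N"].to_numpy(dtype=float)
            c14 = df.loc[need_delta, "count_14N"].to_numpy(dtype=float)
            df.loc[need_delta, "delta_permil"] = compute_delta(
                c15, c14, self.config.r_standard)
        return df

    def fit(self, seed: Optional[int] = None) -> "TrophicResponseResults":
        """Run every stage and return the results object.

        ``seed`` overrides ``config.rng_seed``; it drives the permutation
        null of the phylogenetic-signal stage (the only stochastic stage).
        """
        cfg = self.config
        rng_seed = cfg.rng_seed if seed is None else int(seed)
        exclusions: list[tuple[str, str]] = []

        estimates: dict[tuple[str, str], HceEstimate] = {}
        assignments: dict[str, GuildAssignment] = {}
        for taxon, spots in self.data.groupby("taxon_id", observed=True):
            try:
                for est in fit_taxon_hces(
                        spots, min_spots=cfg.min_spots,
                        enrichment_alpha=cfg.enrichment_alpha,
                        require_positive_mean=cfg.require_positive_mean):
                    estimates[(str(taxon), est.treatment)] = est
            except DegenerateDesignError as exc:
                exclusions.append((str(taxon), f"degenerate design: {exc}"))
                continue
            try:
                assignments[str(taxon)] = assign_guild(
                    spots, alpha=cfg.alpha, min_spots=cfg.min_spots,
                    model=cfg.ancova_model, correction=cfg.posthoc_correction)
            except (InsufficientDataError, DegenerateDesignError) as exc:
                exclusions.append((str(taxon), f"guild classification: {exc}"))

        ref = cfg.activity_reference
        ref_enriched = [e for (t, tr), e in estimates.items()
                        if tr == ref and e.enriched]
        activity_classes, activity_report = rank_activity(
            ref_enriched, cutoff_fraction=cfg.activity_cutoff_fraction)
        activity_of = {c.taxon_id: c.activity for c in activity_classes}

        ternary_points: list[TernaryPoint] = []
        taxa = sorted({t for (t, _) in estimates})
        for taxon in taxa:
            ests = {tr: estimates.get((taxon, tr)) for tr in TREATMENTS}
            if any(e is None for e in ests.values()):
                exclusions.append((taxon, "ternary: missing treatment fit"))
                continue
            if not any(e.enriched for e in ests.values()):
                continue  # not isotopically enriched: not plotted
            guild = assignments[taxon].guild if taxon in assignments else None
            point = normalize_hce([ests[tr].slope for tr in TREATMENTS],
                                  taxon_id=taxon, guild=guild)
            if point is None:
                exclusions.append((taxon, "ternary: no positive HCE component"))
            else:
                ternary_points.append(point)

        phylo: dict[str, PhyloCharacter] = {}
        if self.tree is not None and assignments:
            guild_of = {t: a.guild for t, a in assignments.items()}
            phylo = test_all_guilds(self.tree, guild_of,
                                    n_reshuffles=cfg.n_reshuffles,
                                    rng_seed=rng_seed)
        elif self.tree is None:
            logger.warning("no tree supplied: phylogenetic-signal stage skipped")

        for taxon, reason in exclusions:
            logger.info("excluded %s (%s)", taxon, reason)

        return TrophicResponseResults(
            model=self, estimates=estimates, assignments=assignments,
            activity_report=activity_report, activity_of=activity_of,
            ternary_points=ternary_points, phylo=phylo,
            exclusions=exclusions, rng_seed=rng_seed)


class TrophicResponseResults:
    """Fitted estimates, classifications and diagnostics of one run."""

    def __init__(self, model: TrophicResponseModel,
                 estimates: dict, assignments: dict,
                 activity_report: pd.DataFrame, activity_of: dict,
                 ternary_points: list, phylo: dict,
                 exclusions: list, rng_seed: int):
        self.model = model
        self.estimates = estimates
        self.assignments = assignments
        self.activity_report = activity_report
        self.activity_of = activity_of
        self.ternary_points = ternary_points
        self.phylo = phylo
        self.exclusions = exclusions
        self.rng_seed = rng_seed

    # ------------------------------------------------------------------ #
    @property
    def guild_counts(self) -> dict[str, int]:
        counts = {g: 0 for g in GUILDS}
        for a in self.assignments.values():
            counts[a.guild] += 1
        return counts

    @property
    def activity_counts(self) -> dict[str, int]:
        counts = {"HIGH": 0, "LOW": 0}
        for v in self.activity_of.values():
            counts[v] += 1
        return counts

    def hce_frame(self) -> pd.DataFrame:
        """Long-format HCE table: one row per (taxon, treatment) fit."""
        rows = [dataclasses.asdict(e) for e in self.estimates.values()]
        df = pd.DataFrame(rows)
        return df.sort_values(["taxon_id", "treatment"]).reset_index(drop=True)

    def results_table(self) -> pd.DataFrame:
        """Wide per-taxon table (the schema written by ``to_files``)."""
        taxa = sorted({t for (t, _) in self.estimates} | set(self.assignments))
        tern = {p.taxon_id: p for p in self.ternary_points}
        rows = []
        for taxon in taxa:
            row: dict = {"taxon_id": taxon}
            for tr in TREATMENTS:
                est = self.estimates.get((taxon, tr))
                row[f"hce_{tr}"] = est.slope if est else np.nan
                row[f"se_{tr}"] = est.slope_se if est else np.nan
                row[f"enriched_{tr}"] = est.enriched if est else pd.NA
            row["activity"] = self.activity_of.get(taxon, pd.NA)
            a = self.assignments.get(taxon)
            row["guild"] = a.guild if a else pd.NA
            row["ancova_p"] = a.ancova_p if a else np.nan
            p = tern.get(taxon)
            row["w_H"] = p.w_H if p else np.nan
            row["w_M"] = p.w_M if p else np.nan
            row["w_L"] = p.w_L if p else np.nan
            rows.append(row)
        return pd.DataFrame(rows, columns=RESULT_COLUMNS)

    def run_summary(self) -> dict:
        """JSON-ready summary: tallies, p-values, config echo, seed, version."""
        return {
            "software": {"name": "chipsip", "version": _version},
            "rng_seed": self.rng_seed,
            "n_taxa_classified": len(self.assignments),
            "guild_counts": self.guild_counts,
            "activity_counts": self.activity_counts,
            "activity_cutoff": float(self.activity_report.attrs.get("cutoff", np.nan))
            if len(self.activity_report) else None,
            "phylo_signal": {g: c.to_dict() for g, c in sorted(self.phylo.items())},
            "n_excluded": len(self.exclusions),
            "exclusions": [{"taxon_id": t, "reason": r} for t, r in self.exclusions],
            "config": self.model.config.to_dict(),
        }

    def summary(self) -> str:
        """Human-readable run summary table."""
        counts = self.guild_counts
        lines = [
            "Trophic response analysis",
            "=" * 60,
            f"taxa classified: {len(self.assignments)}"
            f"   (excluded: {len(self.exclusions)})",
            "",
            "guild                pattern      n",
            "-" * 40,
        ]
        for g in GUILDS:
            lines.append(f"{g:<20} {GUILD_PATTERNS[g]:<10} {counts[g]:>4}")
        act = self.activity_counts
        lines += [
            "-" * 40,
            f"activity (ref {self.model.config.activity_reference}, "
            f"{self.model.config.activity_cutoff_fraction:.0%} of max): "
            f"HIGH {act['HIGH']}, LOW {act['LOW']}",
        ]
        if self.phylo:
            lines += ["", "phylogenetic signal (tip-reshuffling null)",
                      "-" * 60,
                      "guild                score  null mean   p_emp    p_F"]
            for g, c in sorted(self.phylo.items()):
                pf = "n/a" if np.isnan(c.p_ftest) else f"{c.p_ftest:.3g}"
                lines.append(
                    f"{g:<20} {c.observed_score:>5}  {c.null_mean:>9.2f}"
                    f"  {c.p_empirical:>7.4g}  {pf:>6}")
        return "\n".join(lines)

    # ------------------------------------------------------------------ #
    def plot_ternary(self, path: str) -> bool:
        return render_ternary(self.ternary_points, path)

    def plot_null_histogram(self, guild: str, path: str) -> None:
        if guild not in self.phylo:
            raise ChipSipError(f"no phylogenetic-signal result for guild {guild!r}")
        plot_null_histogram(self.phylo[guild], path)

    def to_files(self, outdir: str, plots: bool = True) -> dict[str, str]:
        """Write results TSV, summary JSON and (optionally) plots to ``outdir``."""
        import os
        os.makedirs(outdir, exist_ok=True)
        paths = {}
        paths["results"] = os.path.join(outdir, "results.tsv")
        write_results(self.results_table(), paths["results"])
        paths["summary"] = os.path.join(outdir, "summary.json")
        with open(paths["summary"], "w") as fh:
            json.dump(self.run_summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        if plots:
            if self.ternary_points:
                paths["ternary"] = os.path.join(outdir, "ternary.svg")
                self.plot_ternary(paths["ternary"])
            for guild, char in self.phylo.items():
                key = f"null_{guild}"
                paths[key] = os.path.join(outdir, f"null_{guild}.svg")
                plot_null_histogram(char, paths[key])
        return paths
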