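"""End-to-end pipeline: orthologs -> bias screen -> homeolog model -> DE ->
patterns -> enrichment, with a JSON report shaped like the field's standard
summaries (bias class counts per form, cross-form 3x3 table with the
maternal-specific count, percent-DE per contrast, pattern proportions with
balance tests, and the between-form crosslink breakdown).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import CountMatrix
from .bias_screen import estimate_misassignment, pooled_misassignment, screen_mapping_bias
from .de import NBExpressionModel, qc_filter
from .enrichment import read_term_map, term_enrichment
from .homeolog import HomeologBiasModel, assign_categories, compare_forms
from .orthologs import (
    filter_pairs,
    intersect_with_groups,
    pairs_to_frame,
    read_blast6,
    reciprocal_best_hits,
)
from .patterns import (
    NON_ADDITIVE,
    classify_patterns,
    crosslink,
    de_directions,
    eld_balance_test,
    nonadditive_comparison,
    summarize_patterns,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class FormSpec:
    """One polyploid form: its counts, optional homeolog counts, parentage."""

    name: str
    counts: str
    maternal_parent: str  # "A" or "B"
    homeolog_counts: str | None = None

    def __post_init__(self):
        if self.maternal_parent not in ("A", "B"):
            raise ValueError("maternal_parent must be 'A' or 'B'")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seed for a full pipeline run."""

    parent_A_counts: str
    parent_B_counts: str
    forms: list[FormSpec]
    assignment_counts: str | None = None
    hits_ab: str | None = None
    hits_ba: str | None = None
    single_copy_groups: str | None = None
    term_map: str | None = None
    gene_lengths: str | None = None
    alpha: float = 0.05
    cross_threshold: float = 0.5
    min_reads: int = 10
    min_total: int = 10
    min_mean_norm: float = 1.0
    grid_points: int = 2001
    level: float = 0.95
    max_evalue: float = 1e-10
    min_identity: float = 80.0
    min_length: int = 200
    seed: int = 0

    def __post_init__(self):
        if not 1 <= len(self.forms) <= 2:
            raise ValueError("expected one or two polyploid forms")
        self.forms = [f if isinstance(f, FormSpec) else FormSpec(**f) for f in self.forms]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding for display percentages."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_counts_table(class_counts: dict) -> pd.DataFrame:
    """Counts with one-decimal percentages (half-up); totals preserved."""
    total = sum(class_counts.values())
    if total == 0:
        raise ValueError("zero total count")
    if any(v < 0 for v in class_counts.values()):
        raise ValueError("negative class count")
    return pd.DataFrame(
        {
            "count": pd.Series(class_counts),
            "percent": pd.Series(
                {k: round_half_up(100.0 * v / total) for k, v in class_counts.items()}
            ),
        }
    )


def _load_counts(path, group) -> CountMatrix:
    cm = CountMatrix.from_tsv(path)
    cm.samples["group"] = group
    return cm


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run every stage and return (and optionally write) the report bundle.

    Stages with missing inputs (e.g. homeolog counts withheld for a form)
    are marked ``absent`` in the report rather than failing.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "run": {"seed": config.seed, "version": __version__, "alpha": config.alpha},
        "attrition": {},
        "forms": {},
    }

    # ---------------------------------------------------------- orthologs
    locus_universe = None
    if config.hits_ab and config.hits_ba:
        hits_ab = _stage("orthologs", read_blast6, config.hits_ab)
        hits_ba = _stage("orthologs", read_blast6, config.hits_ba)
        pairs = _stage("orthologs", reciprocal_best_hits, hits_ab, hits_ba)
        n_rbh = len(pairs)
        pairs = filter_pairs(
            pairs,
            max_evalue=config.max_evalue,
            min_identity=config.min_identity,
            min_length=config.min_length,
        )
        n_filtered = len(pairs)
        if config.single_copy_groups:
            groups = pd.read_csv(config.single_copy_groups, sep="\t")
            pairs = _stage("orthologs", intersect_with_groups, pairs, groups)
        pair_frame = pairs_to_frame(pairs)
        if out is not None:
            pair_frame.to_csv(out / "ortholog_pairs.tsv", sep="\t", index=False)
        locus_universe = set(pair_frame["id_A"])
        report["orthologs"] = {
            "n_rbh": n_rbh,
            "n_after_similarity_filter": n_filtered,
            "n_final_pairs": len(pairs),
        }
        report["attrition"]["orthologs"] = {
            "input": n_rbh,
            "kept": len(pairs),
            "removed": n_rbh - len(pairs),
        }
    else:
        report["orthologs"] = "absent"

    # --------------------------------------------------------- bias screen
    q_table = None
    unbiased_mapping = None
    if config.assignment_counts:
        assign = pd.read_csv(config.assignment_counts, sep="\t")
        labels = _stage(
            "bias_screen",
            screen_mapping_bias,
            assign,
            cross_threshold=config.cross_threshold,
            min_reads=config.min_reads,
        )
        q_table = _stage("bias_screen", estimate_misassignment, assign)
        unbiased_mapping = set(labels.index[labels == "unbiased_mapping"])
        report["bias_screen"] = {
            "n_loci": int(len(labels)),
            "n_unbiased_mapping": int((labels == "unbiased_mapping").sum()),
            "n_biased_mapping": int((labels == "biased_mapping").sum()),
            "n_indeterminate": int((labels == "indeterminate").sum()),
            "pooled_q": list(pooled_misassignment(assign)),
        }
        report["attrition"]["bias_screen"] = {
            "input": int(len(labels)),
            "kept": len(unbiased_mapping),
            "removed": int(len(labels)) - len(unbiased_mapping),
        }
        if out is not None:
            labels.rename_axis("locus_id").to_frame().to_csv(
                out / "mapping_bias.tsv", sep="\t"
            )
            q_table.to_csv(out / "misassignment.tsv", sep="\t", index=False)
    else:
        report["bias_screen"] = "absent"

    # ------------------------------------------------------------- per form
    cm_A = _stage("counts", _load_counts, config.parent_A_counts, "parentA")
    cm_B = _stage("counts", _load_counts, config.parent_B_counts, "parentB")

    form_bias: dict[str, pd.Series] = {}
    form_patterns: dict[str, pd.Series] = {}
    form_models: dict[str, NBExpressionModel] = {}
    form_nonadd: dict[str, tuple[int, int]] = {}

    for form in config.forms:
        cm_M = _stage("counts", _load_counts, form.counts, form.name)
        joint = cm_A.hstack(cm_B).hstack(cm_M)
        if locus_universe is not None:
            keep = [l for l in joint.loci if l in locus_universe]
            joint = joint.subset_loci(keep)
        n_in = joint.n_loci
        joint, removal = _stage(
            "qc_filter", qc_filter, joint, min_mean_norm=config.min_mean_norm
        )
        report["attrition"][f"qc_{form.name}"] = {
            "input": n_in,
            "kept": joint.n_loci,
            "removed": n_in - joint.n_loci,
        }
        model = NBExpressionModel(joint, alpha=config.alpha)
        form_models[form.name] = model
        de_MA = _stage("de", model.fit_contrast, form.name, "parentA")
        de_MB = _stage("de", model.fit_contrast, form.name, "parentB")
        de_AB = _stage("de", model.fit_contrast, "parentA", "parentB")
        de_mpv = _stage("de", model.fit_mpv, form.name, "parentA", "parentB")

        pat = _stage(
            "patterns",
            classify_patterns,
            de_directions(de_MA),
            de_directions(de_MB),
            de_directions(de_AB),
        )
        form_patterns[form.name] = pat["pattern"]
        pat_summary = summarize_patterns(pat["pattern"])
        n_eld_a = int((pat["pattern"] == "eld_A").sum())
        n_eld_b = int((pat["pattern"] == "eld_B").sum())
        eld_test = (
            eld_balance_test(n_eld_a, n_eld_b) if n_eld_a + n_eld_b else (None, None)
        )
        non_add = int(pat["pattern"].isin(NON_ADDITIVE).sum())
        form_nonadd[form.name] = (non_add, len(pat))

        form_report = {
            "maternal_parent": form.maternal_parent,
            "n_loci_tested": int(len(pat)),
            "contrasts": {
                f"{form.name}_vs_parentA": de_MA.percent_de(),
                f"{form.name}_vs_parentB": de_MB.percent_de(),
                "parentA_vs_parentB": de_AB.percent_de(),
                f"{form.name}_vs_MPV": de_mpv.percent_de(),
            },
            "patterns": {
                "counts": {k: int(v) for k, v in pat_summary["count"].items()},
                "percent": {
                    k: round_half_up(v) for k, v in pat_summary["percent"].items()
                },
                "eld_balance_chi2": eld_test[0],
                "eld_balance_p": eld_test[1],
            },
        }

        # homeolog-specific expression (needs homeolog counts)
        if form.homeolog_counts:
            hc = pd.read_csv(form.homeolog_counts, sep="\t")
            if unbiased_mapping is not None:
                hc = hc[hc["locus_id"].isin(unbiased_mapping)]
            q = q_table if q_table is not None else (0.0, 0.0)
            hmodel = HomeologBiasModel(
                hc,
                q=q,
                grid_points=config.grid_points,
                min_total=config.min_total,
            )
            hres = _stage("homeolog", hmodel.fit, config.level)
            form_bias[form.name] = hres.bias_class
            counts = hres.class_counts()
            chi2, p = (
                hres.balance_test()
                if counts["biased_A"] + counts["biased_B"] > 0
                else (None, None)
            )
            cat = assign_categories(de_AB.direction.map(
                {"up_in_first": "A_higher", "up_in_second": "B_higher", "no_de": "no_de"}
            ), hres.bias_class)
            group_counts = cat["group"].value_counts().to_dict()
            form_report["homeolog"] = {
                "class_counts": {k: int(v) for k, v in counts.items()},
                "class_percent": {
                    k: round_half_up(100.0 * v / counts.sum())
                    for k, v in counts.items()
                },
                "balance_chi2": chi2,
                "balance_p": p,
                "n_excluded_low_count": int(len(hres.excluded)),
                "category_groups": {
                    k: int(group_counts.get(k, 0))
                    for k in ("parental_legacy", "absence_of_bias", "novel_bias")
                },
            }
            report["attrition"][f"homeolog_{form.name}"] = {
                "input": int(len(hres.posteriors) + len(hres.excluded)),
                "kept": int(len(hres.posteriors)),
                "removed": int(len(hres.excluded)),
            }
            if out is not None:
                dump = hres.posteriors.copy()
                dump = dump.join(cat, how="left")
                dump.rename_axis("locus_id").to_csv(
                    out / f"homeolog_{form.name}.tsv", sep="\t"
                )
        else:
            form_report["homeolog"] = "absent"

        if out is not None:
            for res in (de_MA, de_MB, de_AB, de_mpv):
                res.frame.rename_axis("locus_id").to_csv(
                    out / f"de_{res.label}_{form.name}.tsv", sep="\t"
                )
            pat.rename_axis("locus_id").to_csv(
                out / f"patterns_{form.name}.tsv", sep="\t"
            )
        report["forms"][form.name] = form_report

    # ------------------------------------------------------- cross-form
    if len(config.forms) == 2:
        f1, f2 = config.forms
        cross: dict = {}
        if f1.name in form_bias and f2.name in form_bias:
            table, maternal = compare_forms(
                form_bias[f1.name],
                form_bias[f2.name],
                maternal_of_form1=f1.maternal_parent,
                maternal_of_form2=f2.maternal_parent,
            )
            cross["bias_3x3"] = {
                r: {c: int(table.loc[r, c]) for c in table.columns} for r in table.index
            }
            cross["n_maternal_specific_bias"] = len(maternal)
            n_shared = int(table.to_numpy().sum())
            n_diff = n_shared - int(
                sum(table.loc[c, c] for c in table.index)
            )
            cross["n_shared_loci"] = n_shared
            cross["n_different_profile"] = n_diff
        else:
            cross["bias_3x3"] = "absent"

        (na1, t1), (na2, t2) = form_nonadd[f1.name], form_nonadd[f2.name]
        odds, fisher_p = nonadditive_comparison(na1, t1, na2, t2)
        cross["nonadditive_fisher"] = {
            "odds_ratio": odds,
            "p_value": fisher_p,
            f"{f1.name}": {"non_additive": na1, "total": t1},
            f"{f2.name}": {"non_additive": na2, "total": t2},
        }

        # DE between forms on their shared filtered loci
        cm1 = _load_counts(f1.counts, f1.name)
        cm2 = _load_counts(f2.counts, f2.name)
        joint = cm1.hstack(cm2)
        shared = joint.loci.intersection(form_patterns[f1.name].index).intersection(
            form_patterns[f2.name].index
        )
        joint = joint.subset_loci(shared)
        model = NBExpressionModel(joint, alpha=config.alpha)
        de_forms = _stage("de", model.fit_contrast, f1.name, f2.name)
        link = crosslink(
            de_forms,
            form_patterns[f1.name],
            form_patterns[f2.name],
            form_bias.get(f1.name),
            form_bias.get(f2.name),
        )
        n_de = int(len(link))
        cross["between_forms"] = {
            "contrast": de_forms.percent_de(),
            "n_de_loci": n_de,
            "n_transgressive_down_in_lower": int(
                link["transgressive_down_in_lower"].sum()
            ),
        }
        if out is not None:
            de_forms.frame.rename_axis("locus_id").to_csv(
                out / "de_between_forms.tsv", sep="\t"
            )
            link.to_csv(out / "crosslink.tsv", sep="\t")
        report["cross_form"] = cross

        # enrichment of between-form DE loci against the tested background
        if config.term_map:
            terms = read_term_map(config.term_map)
            lengths = None
            if config.gene_lengths:
                lt = pd.read_csv(
                    config.gene_lengths, sep="\t", header=None, names=["gene_id", "length"]
                )
                lengths = dict(zip(lt["gene_id"].astype(str), lt["length"]))
            target = list(link.index)
            background = list(de_forms.frame.index)
            enr = _stage(
                "enrichment",
                term_enrichment,
                target,
                background,
                terms,
                lengths=lengths,
                seed=config.seed,
            )
            report["enrichment"] = {
                "n_terms_tested": int(len(enr)),
                "n_enriched": int(enr["enriched"].sum()),
            }
            if out is not None:
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        else:
            report["enrichment"] = "absent"

    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ----------------------------------------------------------------- schema
def report_schema() -> dict:
    with resources.files("polyexpr").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(report: dict) -> None:
    """Structural validation of a report against the bundled schema.

    Raises ``ValueError`` naming the first missing key or type mismatch.
    """
    schema = report_schema()

    def check(node, spec, path):
        for key, sub in spec.get("required", {}).items():
            if key not in node:
                raise ValueError(f"report missing key {path + key!r}")
            val = node[key]
            if isinstance(sub, dict):
                if val == "absent":
                    continue
                if not isinstance(val, dict):
                    raise ValueError(f"{path + key!r} should be an object")
                check(val, sub, path + key + ".")
            elif sub == "number":
                if val is not None and not isinstance(val, (int, float)):
                    raise ValueError(f"{path + key!r} should be numeric")

    check(report, schema, "")
    for name, form in report.get("forms", {}).items():
        check(form, schema["form"], f"forms.{name}.")


def percentages_sum_ok(percent_table: dict, tol: float = 0.1) -> bool:
    """Displayed percentage tables must sum to 100 within rounding slack."""
    vals = [v for k, v in percent_table.items() if k != "non_additive"]
    return abs(sum(vals) - 100.0) <= tol + 1e-9
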