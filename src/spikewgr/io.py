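"""Readers and writers for the on-disk formats.

Genotypes travel as TSV matrices (header of SNP ids, one row per
individual, leading ``id`` column) in either the native {-1, 0, 1} coding
or the {0, 1, 2} minor-allele-dosage dialect, or as PLINK ``.raw`` exports
(FID IID PAT MAT SEX PHENOTYPE then dosage columns).  SNP maps, phenotypes
and covariates are TSVs keyed by SNP or individual id.  Missing genotypes
are rejected at import with a count, since the model assumes a complete
matrix (pre-impute upstream).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import GenotypeTable, TraitVector
from .significance import EffectTestRecord, DEFAULT_ALPHAS
from .simulate import SimulatedDataset
from .solver import FitResult, ModelSpec
from .onelocus import PriorSpec

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_snp_map",
    "read_phenotypes",
    "read_covariates",
    "write_effect_table",
    "read_effect_table",
    "write_report",
    "write_dataset",
    "read_dataset",
    "write_fit",
    "read_fit",
    "write_manifest",
]

GENOTYPE_DIALECTS = ("pm1", "dosage", "plink-raw")
_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def read_genotypes(
    path,
    dialect: str = "pm1",
    snp_map: pd.DataFrame | None = None,
    maf: np.ndarray | None = None,
) -> GenotypeTable:
    """Read a genotype matrix; ``dialect`` selects the input coding.

    ``pm1``: entries in {-1, 0, 1}; ``dosage``: {0, 1, 2} converted by
    X = dosage - 1; ``plink-raw``: whitespace-separated PLINK export with
    the six metadata columns, dosages {0, 1, 2}.
    """
    if dialect not in GENOTYPE_DIALECTS:
        raise ValueError(f"unknown genotype dialect {dialect!r}; choose from {GENOTYPE_DIALECTS}")
    if dialect == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+")
        ids = df["IID"].astype(str).to_numpy()
        snp_cols = [c for c in df.columns if c not in _PLINK_META]
        mat = df[snp_cols].to_numpy()
        snp_ids = [c.rsplit("_", 1)[0] for c in snp_cols]
    else:
        df = pd.read_csv(path, sep="\t")
        first = df.columns[0]
        if first.lower() in ("id", "iid", "individual"):
            ids = df[first].astype(str).to_numpy()
            df = df.drop(columns=[first])
        else:
            ids = np.array([str(i) for i in range(len(df))])
        snp_ids = list(df.columns)
        mat = df.to_numpy()
    n_missing = int(pd.isna(mat).sum())
    if n_missing:
        raise ValueError(f"{n_missing} missing genotype calls; impute before import")
    mat = np.asarray(mat, dtype=float)
    if not np.all(mat == np.round(mat)):
        raise ValueError("non-integer genotype codes")
    mat = mat.astype(np.int8)
    if dialect in ("dosage", "plink-raw"):
        if mat.min() < 0 or mat.max() > 2:
            raise ValueError("dosage dialect expects codes in {0, 1, 2}")
        mat = mat - 1
    if pd.Series(ids).duplicated().any():
        dups = pd.Series(ids)[pd.Series(ids).duplicated()].tolist()
        raise ValueError(f"duplicated individual ids: {dups}")
    if snp_map is None:
        snp_map = pd.DataFrame({"id": snp_ids, "chrom": 0, "cM": np.nan, "bp": -1})
    else:
        snp_map = snp_map.set_index("id").loc[snp_ids].reset_index()
    return GenotypeTable(codes=mat, snp_map=snp_map, maf=maf, individual_ids=ids)


def write_genotypes(path, table: GenotypeTable) -> None:
    ids = table.individual_ids
    if ids is None:
        ids = np.array([f"ind{i}" for i in range(table.n)])
    df = pd.DataFrame(table.codes, columns=list(table.snp_map["id"]))
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False)


def read_snp_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "chrom", "cM", "bp"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP map lacks columns {sorted(missing)}")
    return df


def read_phenotypes(path, table: GenotypeTable | None = None, column: str | None = None) -> np.ndarray:
    """Phenotype TSV keyed by individual id; aligned to the genotype table."""
    df = pd.read_csv(path, sep="\t")
    id_col = df.columns[0]
    value_col = column or df.columns[1]
    df[id_col] = df[id_col].astype(str)
    if table is not None and table.individual_ids is not None:
        have = set(df[id_col])
        want = [str(i) for i in table.individual_ids]
        extra = sorted(have - set(want))
        lacking = sorted(set(want) - have)
        if extra or lacking:
            raise ValueError(
                f"phenotype ids do not match genotypes; extra: {extra[:5]}, missing: {lacking[:5]}"
            )
        df = df.set_index(id_col).loc[want].reset_index()
    return df[value_col].to_numpy(dtype=float)


def read_covariates(path, table: GenotypeTable | None = None) -> np.ndarray:
    """Covariate TSV -> full-rank design: numeric columns as-is, categorical
    columns dummy-coded against an explicit reference level, plus intercept."""
    df = pd.read_csv(path, sep="\t")
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    if table is not None and table.individual_ids is not None:
        df = df.set_index(id_col).loc[[str(i) for i in table.individual_ids]].reset_index()
    parts = [np.ones((len(df), 1))]
    for col in df.columns[1:]:
        if pd.api.types.is_numeric_dtype(df[col]):
            parts.append(df[col].to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(df[col], drop_first=True)
            parts.append(dummies.to_numpy(dtype=float))
    return np.hstack(parts)


def write_effect_table(path, records: list[EffectTestRecord], snp_ids: list[str], alphas=DEFAULT_ALPHAS) -> None:
    """Stream the significance records to TSV (one row per coordinate)."""
    with open(path, "w") as fh:
        sig_cols = "\t".join(f"sig_moe_{a:g}" for a in alphas)
        fh.write(f"kind\tsnp_i\tsnp_j\tghat\tkappa\tmoe\tlog10_bf\t{sig_cols}\tsig_bf\n")
        for rec in records:
            i = snp_ids[rec.loci[0]]
            j = snp_ids[rec.loci[1]] if len(rec.loci) == 2 else ""
            flags = "\t".join(str(int(rec.significant_moe(a))) for a in alphas)
            fh.write(
                f"{rec.kind}\t{i}\t{j}\t{rec.ghat:.10g}\t{rec.kappa:.10g}\t{rec.moe:.10g}\t"
                f"{rec.log_bayes_factor / np.log(10):.10g}\t{flags}\t{int(rec.significant_bf)}\n"
            )


def read_effect_table(path, snp_ids: list[str]) -> list[EffectTestRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_i": str, "snp_j": str})
    index = {s: k for k, s in enumerate(snp_ids)}
    records = []
    for row in df.itertuples(index=False):
        loci = (index[row.snp_i],) if (pd.isna(row.snp_j) or row.snp_j == "") else (index[row.snp_i], index[row.snp_j])
        records.append(
            EffectTestRecord(
                kind=row.kind,
                loci=loci,
                ghat=row.ghat,
                kappa=row.kappa,
                moe=row.moe,
                log_bayes_factor=row.log10_bf * np.log(10),
            )
        )
    return records


def write_report(path, report_dict: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report_dict, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_manifest(outdir: Path, config: dict, started: float) -> None:
    import platform

    manifest = {
        "config": config,
        "wall_time_s": round(time.time() - started, 3),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    write_report(Path(outdir) / "manifest.json", manifest)


def write_dataset(outdir, dataset: SimulatedDataset) -> None:
    """Serialize a simulated dataset: genotype TSVs, SNP map, phenotype,
    true genetic values, pedigree and the truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in (("training", dataset.training), ("validation", dataset.validation)):
        if table.individual_ids is None:
            table.individual_ids = np.array([f"{name[0]}{i}" for i in range(table.n)])
        write_genotypes(outdir / f"{name}_genotypes.tsv", table)
    cols = ["id", "chrom", "cM", "bp"] + (["causative"] if "causative" in dataset.training.snp_map else [])
    dataset.training.snp_map[cols].to_csv(outdir / "snp_map.tsv", sep="\t", index=False)
    dataset.pedigree.to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
    pd.DataFrame({"maf": dataset.training.maf}).to_csv(outdir / "maf.tsv", sep="\t", index=False)
    if dataset.trait is not None:
        pd.DataFrame(
            {
                "id": dataset.training.individual_ids,
                "trait": dataset.trait.values + dataset.trait.center,
                "genetic_value": dataset.genetic_values_training,
            }
        ).to_csv(outdir / "training_phenotypes.tsv", sep="\t", index=False)
        pd.DataFrame(
            {
                "id": dataset.validation.individual_ids,
                "genetic_value": dataset.genetic_values_validation,
            }
        ).to_csv(outdir / "validation_genetic_values.tsv", sep="\t", index=False)
    truth = {k: v for k, v in dataset.truth.items()}
    from dataclasses import asdict

    write_report(outdir / "truth.json", {"config": asdict(dataset.config), "truth": truth})


def read_dataset(outdir) -> SimulatedDataset:
    outdir = Path(outdir)
    from .simulate import SimulationConfig

    blob = json.loads((outdir / "truth.json").read_text())
    cfg = SimulationConfig(**blob["config"])
    snp_map = read_snp_map(outdir / "snp_map.tsv")
    maf = pd.read_csv(outdir / "maf.tsv", sep="\t")["maf"].to_numpy()
    # maf supplied explicitly: the stored codes are already oriented to the
    # training-set minor allele, which must not be re-derived per file
    training = read_genotypes(outdir / "training_genotypes.tsv", snp_map=snp_map, maf=maf)
    validation = read_genotypes(outdir / "validation_genotypes.tsv", snp_map=snp_map, maf=maf)
    pedigree = pd.read_csv(outdir / "pedigree.tsv", sep="\t")
    ds = SimulatedDataset(
        config=cfg, training=training, validation=validation, pedigree=pedigree, truth=blob["truth"]
    )
    for key in ("causative_bp", "causative_chrom", "additive_effects", "dominance_effects"):
        if key in ds.truth:
            ds.truth[key] = np.asarray(ds.truth[key])
    pheno_path = outdir / "training_phenotypes.tsv"
    if pheno_path.exists():
        pheno = pd.read_csv(pheno_path, sep="\t")
        raw = pheno["trait"].to_numpy(dtype=float)
        ds.trait = TraitVector(values=raw - raw.mean(), center=float(raw.mean()))
        ds.genetic_values_training = pheno["genetic_value"].to_numpy(dtype=float)
        gv = pd.read_csv(outdir / "validation_genetic_values.tsv", sep="\t")
        ds.genetic_values_validation = gv["genetic_value"].to_numpy(dtype=float)
    return ds


def write_fit(outdir, fit: FitResult, snp_ids: list[str]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for kind, eff in fit.effects.items():
        if isinstance(eff, dict):
            rows.extend(
                {"kind": kind, "snp_i": snp_ids[i], "snp_j": snp_ids[j], "ghat": v}
                for (i, j), v in sorted(eff.items())
            )
        else:
            rows.extend(
                {"kind": kind, "snp_i": snp_ids[j], "snp_j": "", "ghat": v} for j, v in enumerate(eff)
            )
    pd.DataFrame(rows).to_csv(outdir / "effects.tsv", sep="\t", index=False)
    pd.DataFrame({"residual": fit.residual}).to_csv(outdir / "residual.tsv", sep="\t", index=False)
    meta = {
        "kinds": list(fit.model.kinds),
        "sigma_e2": fit.sigma_e2,
        "sweeps_run": fit.sweeps_run,
        "converged": fit.converged,
        "tol": fit.model.tol,
        "prior_main": {"gamma": fit.priors["main"].gamma, "lam": fit.priors["main"].lam},
        "prior_epi": None
        if fit.priors.get("epi") is None
        else {"gamma": fit.priors["epi"].gamma, "lam": fit.priors["epi"].lam},
        "fixed": None if fit.fixed is None else list(map(float, fit.fixed)),
    }
    write_report(outdir / "fit.json", meta)


def read_fit(outdir, snp_ids: list[str]) -> FitResult:
    outdir = Path(outdir)
    meta = json.loads((outdir / "fit.json").read_text())
    index = {s: k for k, s in enumerate(snp_ids)}
    df = pd.read_csv(outdir / "effects.tsv", sep="\t", dtype={"snp_i": str, "snp_j": str})
    effects: dict = {}
    p = len(snp_ids)
    for kind, sub in df.groupby("kind"):
        if kind.startswith("epi_"):
            effects[kind] = {
                (index[r.snp_i], index[r.snp_j]): r.ghat for r in sub.itertuples(index=False)
            }
        else:
            vec = np.zeros(p)
            for r in sub.itertuples(index=False):
                vec[index[r.snp_i]] = r.ghat
            effects[kind] = vec
    for kind in meta["kinds"]:
        if kind.startswith("epi_"):
            effects.setdefault(kind, {})
    residual = pd.read_csv(outdir / "residual.tsv", sep="\t")["residual"].to_numpy()
    model = ModelSpec(kinds=tuple(meta["kinds"]), tol=meta["tol"])
    priors = {"main": PriorSpec(**meta["prior_main"])}
    priors["epi"] = None if meta["prior_epi"] is None else PriorSpec(**meta["prior_epi"])
    return FitResult(
        effects=effects,
        fixed=None if meta["fixed"] is None else np.asarray(meta["fixed"]),
        sigma_e2=meta["sigma_e2"],
        sweeps_run=meta["sweeps_run"],
        converged=meta["converged"],
        residual=residual,
        model=model,
        priors=priors,
    )
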