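"""File formats, study configuration and report rendering.

The canonical dataset format is a whitespace-delimited text table with a
header row ``ID G Y1 .. Yk``: one row per individual, ``G`` the additive
genotype (minor-allele dosage) and ``Y*`` the trait values.  Write-only
exporters for PLINK-style .ped/.map and SNPTEST-style .gen/.sample files are
provided for interoperability; the .gen dialect can also be read back, in
which case genotype probabilities are collapsed to expected dosages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ScenarioSpec, SimDataset, scenario_grid, unequal_h2_grid

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_ped_map",
    "write_gen_sample",
    "StudyConfig",
    "load_config",
    "config_hash",
    "write_results",
    "report",
    "plot_power",
]


def write_dataset(path, dataset: SimDataset | tuple) -> None:
    """Write a dataset as the canonical ``ID G Y1..Yk`` text table."""
    if isinstance(dataset, SimDataset):
        g, y = dataset.genotype, dataset.traits
    else:
        g, y = dataset
    y = np.atleast_2d(np.asarray(y, dtype=float))
    k = y.shape[1]
    df = pd.DataFrame({"ID": [f"ind{i + 1}" for i in range(len(g))], "G": g})
    for j in range(k):
        df[f"Y{j + 1}"] = y[:, j]
    df.to_csv(path, sep=" ", index=False, float_format="%.17g")


def read_dataset(path, dialect: str = "table", allow_dosage: bool = False):
    """Read a dataset; returns a :class:`SimDataset` (without ground truth).

    ``dialect="table"`` reads the canonical text table (hard-call genotypes
    in {0,1,2} unless ``allow_dosage``); ``dialect="gen"`` reads a
    SNPTEST-style .gen/.sample pair (pass the .gen path; probabilities are
    collapsed to expected dosages, always non-integer-safe).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "table":
        if path.stat().st_size == 0:
            raise ValueError(f"{path}: empty dataset file")
        df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
        for col in ("ID", "G"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column {col!r}")
        ycols = [c for c in df.columns if c.startswith("Y")]
        if not ycols:
            raise ValueError(f"{path}: no trait columns (Y1..Yk) found")
        g = df["G"].to_numpy(dtype=float)
        bad = np.flatnonzero(~np.isin(g, (0.0, 1.0, 2.0)))
        if bad.size and not allow_dosage:
            raise ValueError(
                f"{path}: non-{{0,1,2}} genotype at data line {bad[0] + 1}"
            )
        y = df[ycols].to_numpy(dtype=float)
        if np.isnan(y).any() or np.isnan(g).any():
            row = int(np.argwhere(np.isnan(y).any(axis=1) | np.isnan(g))[0][0])
            raise ValueError(f"{path}: malformed value at data line {row + 1}")
        geno = g if allow_dosage else g.astype(np.int64)
        return SimDataset(genotype=geno, traits=y)
    if dialect == "gen":
        return _read_gen_sample(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_gen_sample(prefix, dataset: SimDataset, snp_id: str = "rs1") -> None:
    """Write SNPTEST-style ``<prefix>.gen`` and ``<prefix>.sample`` files.

    .gen column order: chromosome, SNP id, position, alleleA, alleleB, then
    per individual the probabilities of (AA, AB, BB) with B the minor/effect
    allele; hard calls become degenerate probability triplets.  .sample has
    the two SNPTEST header lines, phenotype columns typed ``P``.
    """
    prefix = Path(prefix)
    g, y = dataset.genotype, dataset.traits
    probs = []
    for v in g:
        trip = ["0", "0", "0"]
        trip[int(round(v))] = "1"
        probs.extend(trip)
    with open(prefix.with_suffix(".gen"), "w") as fh:
        fh.write("1 " + snp_id + " 1 A B " + " ".join(probs) + "\n")
    k = y.shape[1]
    with open(prefix.with_suffix(".sample"), "w") as fh:
        fh.write("ID_1 ID_2 missing " + " ".join(f"Y{j + 1}" for j in range(k)) + "\n")
        fh.write("0 0 0 " + " ".join("P" for _ in range(k)) + "\n")
        for i in range(len(g)):
            vals = " ".join(f"{v:.17g}" for v in y[i])
            fh.write(f"ind{i + 1} ind{i + 1} 0 {vals}\n")


def _read_gen_sample(gen_path: Path) -> SimDataset:
    gen_path = Path(gen_path)
    sample_path = gen_path.with_suffix(".sample")
    if not sample_path.exists():
        raise FileNotFoundError(sample_path)
    fields = gen_path.read_text().split()
    if len(fields) < 8:
        raise ValueError(f"{gen_path}: malformed .gen line")
    probs = np.array(fields[5:], dtype=float)
    if probs.size % 3:
        raise ValueError(f"{gen_path}: probability count not a multiple of 3")
    probs = probs.reshape(-1, 3)
    dosage = probs @ np.array([0.0, 1.0, 2.0])
    df = pd.read_csv(sample_path, sep=r"\s+", skiprows=[1])
    ycols = [c for c in df.columns if c.startswith("Y")]
    y = df[ycols].to_numpy(dtype=float)
    if y.shape[0] != dosage.shape[0]:
        raise ValueError("sample/gen individual counts disagree")
    return SimDataset(genotype=dosage, traits=y)


def write_ped_map(prefix, dataset: SimDataset, snp_id: str = "rs1") -> None:
    """Write PLINK-style ``<prefix>.ped`` / ``<prefix>.map`` (hard calls only).

    .ped column order: FID IID father mother sex phenotype alleleA alleleB;
    alleles are A (major) and B (minor), genotype = count of B.
    """
    prefix = Path(prefix)
    g = dataset.genotype
    alleles = {0: "A A", 1: "A B", 2: "B B"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, v in enumerate(g):
            fh.write(f"fam{i + 1} ind{i + 1} 0 0 0 -9 {alleles[int(round(v))]}\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        fh.write(f"1 {snp_id} 0 1\n")


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """Configuration of one study run (grid, methods, counts, seed)."""

    seed: int
    methods: list = field(default_factory=lambda: ["uv", "cca"])
    grid: str = "default"  # default | unequal-h2 | inline
    scenarios: list = field(default_factory=list)  # inline ScenarioSpec dicts
    n_replicates: int | None = None
    n_permutations: int | None = None
    alpha: float = 0.05
    output_dir: str = "results"
    priors: dict = field(default_factory=dict)
    pch: dict = field(default_factory=dict)

    def build_scenarios(self) -> list[ScenarioSpec]:
        if self.grid == "default":
            return scenario_grid()
        if self.grid == "unequal-h2":
            return unequal_h2_grid()
        if self.grid == "inline":
            if not self.scenarios:
                raise ValueError("inline grid requires a scenarios list")
            return [
                ScenarioSpec(
                    maf_q=s["maf"],
                    h2=tuple(s["h2"]),
                    effect_sign=tuple(s["effect_sign"]),
                    residual_corr=s.get("residual_corr", 0.0),
                    n_individuals=s.get("n_individuals", 1000),
                    n_replicates=s.get("n_replicates", 1000),
                    n_permutations_per_replicate=s.get("n_permutations", 10),
                    seed=s.get("seed"),
                )
                for s in self.scenarios
            ]
        raise ValueError(f"unknown grid {self.grid!r}")


def load_config(path) -> StudyConfig:
    """Load a YAML or JSON study configuration; the seed is mandatory."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    if "seed" not in data:
        raise ValueError(f"{path}: a seed is mandatory (no wall-clock seeding)")
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return StudyConfig(**data)


def config_hash(config: StudyConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Results and reporting
# ---------------------------------------------------------------------------


def write_results(result, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.thresholds.to_csv(out / "thresholds.tsv", sep="\t", index=False)
    result.power.to_csv(out / "power.tsv", sep="\t", index=False)


def report(results_dir, figure: bool = False) -> str:
    """Render a markdown summary from thresholds.tsv and power.tsv.

    Thresholds are grouped by measure kind (each shown with the achieved
    type-I error, 5% by construction); power is pivoted scenario x method.
    """
    results_dir = Path(results_dir)
    missing = [
        str(results_dir / f)
        for f in ("thresholds.tsv", "power.tsv")
        if not (results_dir / f).exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing result files: {missing}")
    thr = pd.read_csv(results_dir / "thresholds.tsv", sep="\t")
    pw = pd.read_csv(results_dir / "power.tsv", sep="\t")
    lines = ["# Study report", "", "## Empirical significance thresholds", ""]
    for kind, grp in thr.groupby("measure_kind"):
        lines.append(f"### measure: {kind}")
        lines.append("")
        tab = grp.pivot(index="scenario", columns="method", values="threshold")
        tab["type_I_error_%"] = 100 * grp["alpha"].iloc[0]
        lines += ["```", tab.to_string(float_format=lambda v: f"{v:.4g}"), "```", ""]
    lines += ["## Power (%)", ""]
    ptab = pw.pivot(index="scenario", columns="method", values="power")
    lines += ["```", ptab.to_string(float_format=lambda v: f"{v:.1f}"), "```", ""]
    text = "\n".join(lines)
    (results_dir / "report.md").write_text(text)
    if figure:
        plot_power(pw, results_dir / "power.png")
    return text


def plot_power(power_df: pd.DataFrame, path) -> None:
    """Grouped bar chart of power by scenario family (one panel per family)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ptab = power_df.pivot(index="scenario", columns="method", values="power")
    ax = ptab.plot.bar(figsize=(max(8, 0.5 * len(ptab)), 4), width=0.8)
    ax.set_ylabel("power (%)")
    ax.set_xlabel("scenario")
    ax.legend(title="method", fontsize=8)
    plt.tight_layout()
    plt.savefig(path, dpi=120)
    plt.close()
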