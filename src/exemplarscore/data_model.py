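"""Typed containers and readers/writers for the pipeline's inputs and outputs.

The containers are thin wrappers around pandas objects:

* :class:`DataDictionary` — per-variable type and domain declarations for the
  clinical feature table (continuous / ordinal / binary / categorical).
* :class:`ClinicalDataset` — subjects × mixed-type clinical variables with a
  site label, Alda lithium-response total (0–10), and a binary response label
  (responder ⟺ Alda total ≥ 7).
* :class:`GenotypeDataset` — subjects × biallelic SNPs, additively coded
  dosages in {0, 1, 2} with NaN for missing calls.
* :class:`GeneAnnotation` — gene intervals in BED convention (0-based,
  half-open).
* :class:`GeneSetCollection` — GMT-style gene sets.

File dialects are deliberately narrow: clinical tables are UTF-8 TSV with a
header row, missing cells encoded as an empty string or the literal ``NA``
(case-sensitive); genotypes come from VCF v4.x (GT field, biallelic records
only) or a dosage TSV plus variant map; annotation is BED6 with the gene id
in the name column; gene sets are GMT. Anything else is rejected loudly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

VARTYPES = ("continuous", "ordinal", "binary", "categorical")
MISSING_CODES = ("", "NA")

RESERVED_COLUMNS = ("subject_id", "site", "alda_total", "response")


# ---------------------------------------------------------------------------
# Data dictionary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variable:
    """One clinical variable: its measurement type and allowed domain.

    ``domain`` is a list of category strings for binary/categorical variables,
    a ``(low, high)`` tuple for bounded continuous/ordinal variables, or
    ``None`` for unbounded continuous/ordinal variables.
    """

    name: str
    vartype: str
    domain: object = None

    def __post_init__(self) -> None:
        if self.vartype not in VARTYPES:
            raise ValidationError(
                f"variable {self.name!r}: unknown vartype {self.vartype!r}"
            )
        if self.vartype in ("binary", "categorical"):
            if not isinstance(self.domain, (list, tuple)) or len(self.domain) == 0:
                raise ValidationError(
                    f"variable {self.name!r}: categorical domain must be a non-empty list"
                )
            cats = [str(c) for c in self.domain]
            if len(set(cats)) != len(cats):
                raise ValidationError(
                    f"variable {self.name!r}: duplicate categories in domain"
                )
            object.__setattr__(self, "domain", cats)
            if self.vartype == "binary" and len(cats) != 2:
                raise ValidationError(
                    f"variable {self.name!r}: binary domain must have exactly 2 categories"
                )
        else:
            if self.domain is not None:
                lo, hi = self.domain
                lo, hi = float(lo), float(hi)
                if not lo < hi:
                    raise ValidationError(
                        f"variable {self.name!r}: domain interval must satisfy min < max"
                    )
                object.__setattr__(self, "domain", (lo, hi))

    @property
    def is_numeric(self) -> bool:
        return self.vartype in ("continuous", "ordinal")

    def check_value(self, value: object, subject_id: str | None = None) -> None:
        """Raise :class:`ValidationError` if a non-missing value is out of domain."""
        where = f" (subject {subject_id})" if subject_id is not None else ""
        if self.is_numeric:
            try:
                x = float(value)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"variable {self.name!r}{where}: non-numeric value {value!r}"
                ) from None
            if self.domain is not None:
                lo, hi = self.domain
                if not (lo <= x <= hi):
                    raise ValidationError(
                        f"variable {self.name!r}{where}: value {x} outside [{lo}, {hi}]"
                    )
        else:
            if str(value) not in self.domain:
                raise ValidationError(
                    f"variable {self.name!r}{where}: value {value!r} not in domain {self.domain}"
                )


class DataDictionary:
    """Ordered collection of :class:`Variable` records, keyed by name."""

    def __init__(self, variables: Iterable[Variable]):
        self._variables: dict[str, Variable] = {}
        for v in variables:
            if v.name in self._variables:
                raise ValidationError(f"duplicate variable {v.name!r} in dictionary")
            self._variables[v.name] = v

    def __contains__(self, name: str) -> bool:
        return name in self._variables

    def __getitem__(self, name: str) -> Variable:
        return self._variables[name]

    def __iter__(self):
        return iter(self._variables.values())

    def __len__(self) -> int:
        return len(self._variables)

    @property
    def names(self) -> list[str]:
        return list(self._variables)

    def to_json(self, path: str | Path) -> None:
        records = []
        for v in self:
            if v.is_numeric:
                domain = "unbounded" if v.domain is None else list(v.domain)
            else:
                domain = list(v.domain)
            records.append({"name": v.name, "vartype": v.vartype, "domain": domain})
        Path(path).write_text(json.dumps(records, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DataDictionary":
        try:
            records = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"data dictionary {path}: invalid JSON ({exc})") from None
        variables = []
        for rec in records:
            try:
                name, vartype, domain = rec["name"], rec["vartype"], rec["domain"]
            except (KeyError, TypeError):
                raise SchemaError(
                    f"data dictionary {path}: each record needs name/vartype/domain"
                ) from None
            if domain == "unbounded":
                domain = None
            variables.append(Variable(name, vartype, domain))
        return cls(variables)


# ---------------------------------------------------------------------------
# Clinical dataset
# ---------------------------------------------------------------------------

@dataclass
class ClinicalDataset:
    """Multi-site clinical table.

    ``subjects`` is indexed by unique ``subject_id`` and holds the columns
    ``site``, ``alda_total``, ``response`` plus one column per dictionary
    variable (float for continuous/ordinal, string for binary/categorical;
    NaN/None marks missing).
    """

    subjects: pd.DataFrame
    dictionary: DataDictionary

    def __post_init__(self) -> None:
        df = self.subjects
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate subject_id values: {dupes[:5]}")
        for col in ("site", "alda_total", "response"):
            if col not in df.columns:
                raise SchemaError(f"clinical table missing required column {col!r}")
        extra = [
            c for c in df.columns
            if c not in ("site", "alda_total", "response") and c not in self.dictionary
        ]
        if extra:
            raise SchemaError(f"columns not in data dictionary: {extra}")

    @property
    def feature_names(self) -> list[str]:
        return [n for n in self.dictionary.names if n in self.subjects.columns]

    @property
    def features(self) -> pd.DataFrame:
        return self.subjects[self.feature_names]

    @property
    def site(self) -> pd.Series:
        return self.subjects["site"]

    @property
    def response(self) -> pd.Series:
        return self.subjects["response"]

    def validate_domains(self) -> None:
        """Check every non-missing feature value against its dictionary domain."""
        for name in self.feature_names:
            var = self.dictionary[name]
            col = self.subjects[name]
            for sid, value in col.items():
                if _is_missing(value):
                    continue
                var.check_value(value, subject_id=str(sid))

    def write(self, table_path: str | Path, dictionary_path: str | Path | None = None) -> None:
        out = self.subjects.copy()
        out.insert(0, "subject_id", out.index)
        out.to_csv(table_path, sep="\t", index=False, na_rep="NA")
        if dictionary_path is not None:
            self.dictionary.to_json(dictionary_path)


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return False


def alda_response_label(alda_total: int) -> int:
    """Binary lithium-response label from the Alda total: 1 iff total ≥ 7.

    The Alda scale rates long-term lithium response retrospectively on 0–10;
    a total of 7 or more defines a responder.
    """
    try:
        x = float(alda_total)
    except (TypeError, ValueError):
        raise ValidationError(f"Alda total {alda_total!r} is not numeric") from None
    if not (x == int(x) and 0 <= x <= 10):
        raise ValidationError(f"Alda total {alda_total!r} outside integer range [0, 10]")
    return int(x >= 7)


def read_clinical(table_path: str | Path, dictionary_path: str | Path) -> ClinicalDataset:
    """Read and validate a clinical TSV against its JSON data dictionary.

    Missing cells must be empty or the literal ``NA``.  A ``response`` column
    is optional; when absent it is derived from ``alda_total`` via
    :func:`alda_response_label` (left missing where the Alda total is missing).
    """
    dictionary = DataDictionary.from_json(dictionary_path)
    raw = pd.read_csv(
        table_path, sep="\t", dtype=str,
        na_values=list(MISSING_CODES), keep_default_na=False,
    )
    if "subject_id" not in raw.columns:
        raise SchemaError("clinical table has no subject_id column")
    for col in ("site", "alda_total"):
        if col not in raw.columns:
            raise SchemaError(f"clinical table has no {col} column")
    unknown = [
        c for c in raw.columns
        if c not in RESERVED_COLUMNS and c not in dictionary
    ]
    if unknown:
        raise SchemaError(f"columns not in data dictionary: {unknown}")

    raw = raw.set_index("subject_id")
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate subject_id values: {dupes[:5]}")

    out = pd.DataFrame(index=raw.index)
    out["site"] = raw["site"]
    out["alda_total"] = pd.to_numeric(raw["alda_total"], errors="coerce")
    bad_alda = out["alda_total"].dropna()
    for sid, x in bad_alda.items():
        if not (float(x).is_integer() and 0 <= x <= 10):
            raise ValidationError(f"subject {sid}: alda_total {x} outside [0, 10]")
    if "response" in raw.columns:
        resp = pd.to_numeric(raw["response"], errors="coerce")
        bad = resp.dropna()[~resp.dropna().isin([0, 1])]
        if len(bad):
            raise ValidationError(
                f"response values not in {{0,1}} for subjects {bad.index.tolist()[:5]}"
            )
        out["response"] = resp
    else:
        out["response"] = [
            np.nan if math.isnan(a) else alda_response_label(a)
            for a in out["alda_total"]
        ]

    for name in dictionary.names:
        if name not in raw.columns:
            continue
        var = dictionary[name]
        col = raw[name]
        if var.is_numeric:
            numeric = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & numeric.isna()
            if bad.any():
                sid = bad.idxmax()
                raise ValidationError(
                    f"variable {name!r} (subject {sid}): non-numeric value {col[sid]!r}"
                )
            out[name] = numeric
        else:
            out[name] = col.where(col.notna(), None)

    data = ClinicalDataset(out, dictionary)
    data.validate_domains()
    return data


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeDataset:
    """Additively coded biallelic SNP matrix.

    ``variants`` has columns variant_id / chrom / pos / ref / alt (pos is
    1-based, the VCF convention); ``dosages`` is subjects × variant_id with
    float entries in {0, 1, 2} or NaN for missing calls.
    """

    variants: pd.DataFrame
    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.variants
        for col in ("variant_id", "chrom", "pos", "ref", "alt"):
            if col not in v.columns:
                raise SchemaError(f"variant table missing column {col!r}")
        if v["variant_id"].duplicated().any():
            raise ValidationError("duplicate variant_id values in variant table")
        if (v["pos"] <= 0).any():
            raise ValidationError("variant positions must be positive (1-based)")
        if list(self.dosages.columns) != list(v["variant_id"]):
            raise SchemaError("dosage columns do not match the variant table order")
        values = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValidationError("dosage entries must be 0, 1, 2 or missing")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.dosages.index)

    def write_dosage_tsv(self, dosage_path: str | Path, map_path: str | Path) -> None:
        out = self.dosages.copy()
        out.insert(0, "subject_id", out.index)
        out.to_csv(dosage_path, sep="\t", index=False, na_rep="NA", float_format="%g")
        self.variants.to_csv(map_path, sep="\t", index=False)


def read_genotypes_vcf(vcf_path: str | Path) -> GenotypeDataset:
    """Read a biallelic VCF into additive dosages (alt-allele counts).

    GT coding: 0/0 → 0; 0/1 or 1/0 → 1; 1/1 → 2; ./. → missing.  Phased
    separators are treated like unphased ones.  Multiallelic records are
    rejected by name.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for record in vcf:
        if len(record.ALT) != 1:
            raise ValidationError(
                f"multiallelic record at {record.CHROM}:{record.POS} "
                f"({record.REF}->{record.ALT}); only biallelic records are supported"
            )
        vid = record.ID if record.ID not in (None, ".") else (
            f"{record.CHROM}:{record.POS}:{record.REF}:{record.ALT[0]}"
        )
        # gts012: 0/1/2 = alt count, 3 = unknown genotype
        gts = np.asarray(record.gt_types, dtype=float)
        gts[gts == 3] = np.nan
        ids.append(vid)
        chroms.append(record.CHROM)
        poss.append(record.POS)
        refs.append(record.REF)
        alts.append(record.ALT[0])
        rows.append(gts)
    vcf.close()
    if not ids:
        raise SchemaError(f"VCF {vcf_path} contains no records")
    variants = pd.DataFrame(
        {"variant_id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    dosages = pd.DataFrame(
        np.vstack(rows).T, index=pd.Index(samples, name="subject_id"), columns=ids
    )
    return GenotypeDataset(variants, dosages)


def read_genotypes_tsv(dosage_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read the dosage-TSV dialect (subjects as rows) plus its variant map."""
    dosages = pd.read_csv(
        dosage_path, sep="\t", na_values=list(MISSING_CODES), keep_default_na=False,
    )
    if "subject_id" not in dosages.columns:
        raise SchemaError("dosage table has no subject_id column")
    dosages = dosages.set_index("subject_id").astype(float)
    variants = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    variants = variants[["variant_id", "chrom", "pos", "ref", "alt"]]
    dosages = dosages[list(variants["variant_id"])]
    return GenotypeDataset(variants, dosages)


# ---------------------------------------------------------------------------
# Gene annotation and gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """Gene intervals, BED convention: 0-based, half-open [start, end)."""

    genes: pd.DataFrame  # gene_id, chrom, start, end

    def __post_init__(self) -> None:
        g = self.genes
        for col in ("gene_id", "chrom", "start", "end"):
            if col not in g.columns:
                raise SchemaError(f"gene annotation missing column {col!r}")
        if g["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id values in annotation")
        if not (g["start"] < g["end"]).all():
            raise ValidationError("gene intervals must satisfy start < end")


def read_bed(path: str | Path) -> GeneAnnotation:
    """Read BED (≥4 columns; the name column carries the gene id)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise SchemaError(f"BED line has fewer than 4 columns: {line!r}")
        rows.append(
            {"gene_id": parts[3], "chrom": parts[0],
             "start": int(parts[1]), "end": int(parts[2])}
        )
    if not rows:
        raise SchemaError(f"BED file {path} contains no intervals")
    return GeneAnnotation(pd.DataFrame(rows)[["gene_id", "chrom", "start", "end"]])


def write_bed(annotation: GeneAnnotation, path: str | Path) -> None:
    lines = [
        f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene_id}\t0\t+"
        for r in annotation.genes.itertuples()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class GeneSetCollection:
    """GMT-style gene sets: set_id → (description, member gene ids)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, (_desc, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {set_id!r} has no members")
            if len(set(members)) != len(members):
                raise ValidationError(f"gene set {set_id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, tuple[str, list[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"GMT line needs set_id, description, ≥1 member: {line!r}")
        sets[parts[0]] = (parts[1], parts[2:])
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([set_id, desc, *members])
        for set_id, (desc, members) in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")
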