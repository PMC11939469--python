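"""Readers and writers for every external representation the pipeline touches.

Phenotype tables are comma-separated with a header row; ``day`` is an integer
offset from the start of the experimental period (day 0), not a calendar date.
Genotypes travel as PLINK text (.ped/.map) or PLINK 1 binary (.bed/.bim/.fam);
coordinates are 1-based and chromosome labels are kept as strings so "X" and
"1"–"26" coexist without lossy coercion.

Genotype calls are stored as the count of the A1 allele per animal and SNP
(0, 1, 2) with :data:`MISSING` (−1) for no-calls.  When reading PLINK text, A1
is the minor allele determined from observed frequencies (alphabetical
tie-break at frequency exactly 0.5); binary files carry their own A1/A2
columns in the .bim and are trusted as written, so write-then-read round-trips
are lossless.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DuplicateRecordError,
    FormatError,
    TruncationError,
    UnsupportedModeError,
)

logger = logging.getLogger(__name__)

MISSING: int = -1

_BED_MAGIC = b"\x6c\x1b"
# PLINK 1 two-bit codes, little-endian within each byte:
#   00 = homozygous A1, 01 = missing, 10 = heterozygous, 11 = homozygous A2
_BITS_TO_CALL = np.array([2, MISSING, 1, 0], dtype=np.int8)
_CALL_TO_BITS = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class WeightSeries:
    """Longitudinal body-weight observations for one animal within one period.

    ``days`` must be strictly increasing and ``weights_kg`` positive and
    finite; at least two observations are needed before any growth regression
    can be fitted (enforced at fit time, not here).
    """

    animal_id: str
    days: np.ndarray
    weights_kg: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.weights_kg = np.asarray(self.weights_kg, dtype=float)
        if self.days.shape != self.weights_kg.shape:
            raise FormatError(f"{self.animal_id}: days and weights differ in length")
        if np.any(np.diff(self.days) <= 0):
            raise FormatError(f"{self.animal_id}: weigh days must be strictly increasing")
        if not np.all(np.isfinite(self.weights_kg)) or np.any(self.weights_kg <= 0):
            raise FormatError(f"{self.animal_id}: weights must be positive and finite")

    @property
    def n_obs(self) -> int:
        return len(self.days)


@dataclass
class IntakeSeries:
    """Daily as-fed feed intake observations for one animal within one period.

    Days on which the animal recorded nothing are absent observations, never
    zeros: the feed system only logs disappearance when feeding occurs.
    """

    animal_id: str
    days: np.ndarray
    as_fed_kg: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.as_fed_kg = np.asarray(self.as_fed_kg, dtype=float)
        if self.days.shape != self.as_fed_kg.shape:
            raise FormatError(f"{self.animal_id}: days and intakes differ in length")
        if len(np.unique(self.days)) != len(self.days):
            raise DuplicateRecordError(f"{self.animal_id}: duplicate intake day")
        order = np.argsort(self.days)
        self.days = self.days[order]
        self.as_fed_kg = self.as_fed_kg[order]
        if not np.all(np.isfinite(self.as_fed_kg)) or np.any(self.as_fed_kg < 0):
            raise FormatError(f"{self.animal_id}: intakes must be non-negative and finite")

    @property
    def n_obs(self) -> int:
        return len(self.days)


@dataclass
class GenotypeMatrix:
    """Animals × SNPs genotype calls with map positions and allele labels.

    ``calls[i, j]`` is the number of A1 alleles carried by animal *i* at SNP
    *j* (0/1/2), or :data:`MISSING`.  SNPs observed with more than two
    alleles are flagged ``multi_allelic`` with all calls missing; QC removes
    them downstream.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    chromosome: np.ndarray
    position_bp: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    calls: np.ndarray
    multi_allelic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.a1 = np.asarray(self.a1, dtype=object)
        self.a2 = np.asarray(self.a2, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.multi_allelic is None:
            self.multi_allelic = np.zeros(len(self.snp_ids), dtype=bool)
        self.multi_allelic = np.asarray(self.multi_allelic, dtype=bool)
        n, m = self.calls.shape
        if n != len(self.animal_ids):
            raise FormatError("calls rows do not match animal_ids")
        for name, arr in (
            ("chromosome", self.chromosome),
            ("position_bp", self.position_bp),
            ("a1", self.a1),
            ("a2", self.a2),
            ("multi_allelic", self.multi_allelic),
        ):
            if len(arr) != m:
                raise FormatError(f"{name} does not match number of SNPs")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given animal/SNP index arrays."""
        ai = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        sj = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeMatrix(
            animal_ids=[self.animal_ids[i] for i in ai],
            snp_ids=[self.snp_ids[j] for j in sj],
            chromosome=self.chromosome[sj],
            position_bp=self.position_bp[sj],
            a1=self.a1[sj],
            a2=self.a2[sj],
            calls=self.calls[np.ix_(ai, sj)],
            multi_allelic=self.multi_allelic[sj],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.animal_ids == other.animal_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.chromosome, other.chromosome)
            and np.array_equal(self.position_bp, other.position_bp)
            and np.array_equal(self.a1, other.a1)
            and np.array_equal(self.a2, other.a2)
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.multi_allelic, other.multi_allelic)
        )


@dataclass
class PeriodConfig:
    """One experimental period: day window and diet dry-matter fraction."""

    name: str
    start_day: int
    end_day: int
    dm_fraction: float

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ConfigurationError(f"period {self.name}: end_day must exceed start_day")
        if not 0 < self.dm_fraction <= 1:
            raise ConfigurationError(f"period {self.name}: dm_fraction must be in (0, 1]")


@dataclass
class RunConfig:
    """Pipeline-wide settings: periods, QC thresholds, significance, seed."""

    periods: list[PeriodConfig] = field(
        default_factory=lambda: [
            PeriodConfig("period1", 0, 42, 0.906),
            PeriodConfig("period2", 0, 42, 0.897),
        ]
    )
    snp_call_rate_min: float = 0.90
    ind_call_rate_min: float = 0.90
    maf_min: float = 0.05
    alpha: float = 0.05
    covariates: list[str] = field(default_factory=lambda: ["mtbw"])
    dmi_method: str = "midpoint"   # or "mean"
    rfi_size_regressor: str = "mbw"  # or "mtbw"
    seed: int = 20210830

    def __post_init__(self) -> None:
        for name, v in (
            ("snp_call_rate_min", self.snp_call_rate_min),
            ("ind_call_rate_min", self.ind_call_rate_min),
            ("maf_min", self.maf_min),
            ("alpha", self.alpha),
        ):
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must lie strictly between 0 and 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        periods = [PeriodConfig(**p) for p in raw.pop("periods", [])]
        cfg = cls(**raw) if not periods else cls(periods=periods, **raw)
        return cfg

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


# ---------------------------------------------------------------------------
# phenotype / intake / covariate tables
# ---------------------------------------------------------------------------

def _read_long_table(path, value_col: str, *, positive: bool) -> pd.DataFrame:
    # round_trip parsing: the written decimal maps back to the identical double
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"animal_id", "day", value_col}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    values = pd.to_numeric(df[value_col], errors="coerce")
    days = pd.to_numeric(df["day"], errors="coerce")
    bad = values.isna() | ~np.isfinite(values) | days.isna()
    if positive:
        bad |= values <= 0
    else:
        bad |= values < 0
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: row {row + 2} (animal {df['animal_id'].iloc[row]!r}) has "
            f"invalid {value_col} {df[value_col].iloc[row]!r}"
        )
    dup = df.duplicated(subset=["animal_id", "day"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise DuplicateRecordError(
            f"{path}: duplicate (animal, day) = "
            f"({df['animal_id'].iloc[row]!r}, {df['day'].iloc[row]!r}) at row {row + 2}"
        )
    out = df[["animal_id", "day", value_col]].copy()
    out["animal_id"] = out["animal_id"].astype(str)
    out["day"] = days.astype(int)
    out[value_col] = values.astype(float)
    return out


def read_weights(path) -> dict[str, WeightSeries]:
    """Read weights.csv (animal_id, day, weight_kg) into per-animal series."""
    df = _read_long_table(path, "weight_kg", positive=True)
    out: dict[str, WeightSeries] = {}
    for animal, grp in df.groupby("animal_id", sort=True):
        grp = grp.sort_values("day")
        out[str(animal)] = WeightSeries(str(animal), grp["day"].to_numpy(), grp["weight_kg"].to_numpy())
    logger.info("read %d weight records for %d animals from %s", len(df), len(out), path)
    return out


def write_weights(series: dict[str, WeightSeries], path) -> None:
    rows = [
        {"animal_id": s.animal_id, "day": d, "weight_kg": w}
        for s in series.values()
        for d, w in zip(s.days, s.weights_kg)
    ]
    # %.17g guarantees the written decimal round-trips to the same double
    pd.DataFrame(rows, columns=["animal_id", "day", "weight_kg"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_intakes(path) -> dict[str, IntakeSeries]:
    """Read intakes.csv (animal_id, day, as_fed_kg) into per-animal series."""
    df = _read_long_table(path, "as_fed_kg", positive=False)
    out: dict[str, IntakeSeries] = {}
    for animal, grp in df.groupby("animal_id", sort=True):
        out[str(animal)] = IntakeSeries(str(animal), grp["day"].to_numpy(), grp["as_fed_kg"].to_numpy())
    logger.info("read %d intake records for %d animals from %s", len(df), len(out), path)
    return out


def write_intakes(series: dict[str, IntakeSeries], path) -> None:
    rows = [
        {"animal_id": s.animal_id, "day": d, "as_fed_kg": v}
        for s in series.values()
        for d, v in zip(s.days, s.as_fed_kg)
    ]
    pd.DataFrame(rows, columns=["animal_id", "day", "as_fed_kg"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_covariates(path) -> pd.DataFrame:
    """Read covariates.csv; requires animal_id, keeps breed / pwwt_ebv / extras."""
    df = pd.read_csv(path)
    if "animal_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'animal_id'")
    df["animal_id"] = df["animal_id"].astype(str)
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a result table as TSV (the pipeline's output dialect)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# PLINK text (.ped / .map)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read a PLINK .ped/.map pair.

    Allele pair "0 0" is a missing call.  A1 is the minor allele determined
    from observed frequencies (alphabetical tie-break at 0.5).  SNPs with more
    than two observed alleles are flagged multi-allelic and all their calls
    set missing; QC removes them later.
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None, dtype=str)
    if mp.shape[1] != 4:
        raise FormatError(f"{map_path}: expected 4 columns, found {mp.shape[1]}")
    chrom = mp[0].to_numpy(dtype=object)
    snp_ids = mp[1].astype(str).tolist()
    try:
        position_bp = mp[3].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{map_path}: non-integer bp position") from exc
    m = len(snp_ids)

    animal_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}: line {lineno} has {len(fields)} fields, expected {6 + 2 * m}"
                )
            animal_ids.append(fields[1])
            allele_rows.append(fields[6:])
    n = len(animal_ids)
    alleles = np.array(allele_rows, dtype=object).reshape(n, m, 2) if n else np.empty((0, m, 2), object)

    calls = np.full((n, m), MISSING, dtype=np.int8)
    a1 = np.empty(m, dtype=object)
    a2 = np.empty(m, dtype=object)
    multi = np.zeros(m, dtype=bool)
    for j in range(m):
        col = alleles[:, j, :]
        flat = col.ravel()
        observed = flat[flat != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            multi[j] = True
            a1[j], a2[j] = "0", "0"
            continue
        if len(uniq) == 0:
            a1[j], a2[j] = "0", "0"
            continue
        if len(uniq) == 1:
            a1[j], a2[j] = uniq[0], uniq[0]
        else:
            # minor allele first; alphabetical tie-break at exactly 0.5
            order = np.lexsort((uniq, counts))
            if counts[0] == counts[1]:
                order = np.argsort(uniq)
            a1[j], a2[j] = uniq[order[0]], uniq[order[1]]
        ok = (col[:, 0] != "0") & (col[:, 1] != "0")
        calls[ok, j] = (col[ok, 0] == a1[j]).astype(np.int8) + (col[ok, 1] == a1[j]).astype(np.int8)
    return GenotypeMatrix(animal_ids, snp_ids, chrom, position_bp, a1, a2, calls, multi)


# ---------------------------------------------------------------------------
# PLINK 1 binary (.bed / .bim / .fam)
# ---------------------------------------------------------------------------

def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a SNP-major PLINK 1 binary trio; A1/A2 are trusted as written."""
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] != 6:
        raise FormatError(f"{bim_path}: expected 6 columns, found {bim.shape[1]}")
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    animal_ids = fam[1].astype(str).tolist()
    snp_ids = bim[1].astype(str).tolist()
    n, m = len(animal_ids), len(snp_ids)

    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != b"\x01":
        if raw[2:3] == b"\x00":
            raise UnsupportedModeError(f"{bed_path}: individual-major mode is not supported")
        raise FormatError(f"{bed_path}: unknown mode byte {raw[2:3]!r}")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise TruncationError(f"{bed_path}: {len(raw)} bytes, expected {expected} for {n}×{m}")

    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # expand 4 two-bit codes per byte, little-endian within the byte
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    calls = _BITS_TO_CALL[codes[:, :n]].T.copy()

    return GenotypeMatrix(
        animal_ids=animal_ids,
        snp_ids=snp_ids,
        chromosome=bim[0].to_numpy(dtype=object),
        position_bp=bim[3].astype(np.int64).to_numpy(),
        a1=bim[4].to_numpy(dtype=object),
        a2=bim[5].to_numpy(dtype=object),
        calls=calls,
    )


def write_plink_binary(G: GenotypeMatrix, bed_path, bim_path, fam_path) -> None:
    """Write a SNP-major PLINK 1 binary trio; read(write(G)) == G on valid data."""
    if G.multi_allelic.any():
        raise FormatError("cannot write multi-allelic SNPs to PLINK binary; run QC first")
    n, m = G.n_animals, G.n_snps
    bytes_per_snp = (n + 3) // 4
    width = bytes_per_snp * 4

    bits = np.zeros((m, width), dtype=np.uint8)
    call_codes = np.full(256, 0b01, dtype=np.uint8)  # unknown codes encode as missing
    for call, code in _CALL_TO_BITS.items():
        call_codes[call & 0xFF] = code
    bits[:, :n] = call_codes[G.calls.T.astype(np.uint8)]
    bits[:, n:] = 0b00  # PLINK pads trailing slots with zero bits
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= bits[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())

    bim = pd.DataFrame(
        {
            0: G.chromosome,
            1: G.snp_ids,
            2: 0,
            3: G.position_bp,
            4: G.a1,
            5: G.a2,
        }
    )
    bim.to_csv(bim_path, sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {0: G.animal_ids, 1: G.animal_ids, 2: 0, 3: 0, 4: 0, 5: -9}
    )
    fam.to_csv(fam_path, sep="\t", header=False, index=False)
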