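"""Plain-text readers and writers for every pipeline artefact.

All tabular artefacts are tab-separated with a header row: weather
(timestamp, temp_c, rh_pct), day classes (date, max_thi_c, category), pings
(animal_id, date, pings), animal metadata, dosage matrices (first column
``animal_id``, remaining columns marker ids), marker maps (marker_id,
chromosome, position_bp), trait tables, window tables and enrichment tables.
Genotypes can also be round-tripped through the PLINK text dialect
(whitespace-separated .ped/.map with A/C/G/T alleles, 0 = missing); the
dosage convention there is the count of the lexicographically larger allele,
which is immaterial to MAF filtering (allele-label-swap invariant) and only
flips effect signs downstream.  Gene coordinates are read from BED (0-based
half-open, converted to 1-based inclusive) or GFF3; term annotations from a
2- or 3-column TSV (gene_id, term_id[, aspect]).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# ---------------------------------------------------------------- weather


def write_weather(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


# ---------------------------------------------------------------- day classes


def write_day_classes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_day_classes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


# ---------------------------------------------------------------- pings / metadata


def write_pings(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pings(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["pings"] = df["pings"].astype(int)
    return df


def write_meta(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# ---------------------------------------------------------------- traits


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, sep="\t", index=True, index_label="animal_id", na_rep="NA")


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="animal_id", na_values="NA")


# ---------------------------------------------------------------- genotypes


def write_dosages(dosages: pd.DataFrame, path) -> None:
    dosages.to_csv(path, sep="\t", index=True, index_label="animal_id", na_rep="NA")


def read_dosages(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="animal_id", na_values="NA")


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    marker_map.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return df


# ---------------------------------------------------------------- PLINK text dialect


def read_plink(ped_path, map_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read whitespace-separated PLINK .ped/.map into dosages + marker map.

    Dosage is the count of the lexicographically larger of the two observed
    alleles at each marker; '0' alleles mark missing genotypes (NaN dosage).
    Map columns follow PLINK order: chromosome, marker id, genetic distance
    (ignored), bp position (missing/negative -> NaN).
    """
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chromosome", "marker_id", "cm", "position_bp"],
                     dtype={"chromosome": str})
    mp["position_bp"] = pd.to_numeric(mp["position_bp"], errors="coerce")
    mp.loc[mp["position_bp"] <= 0, "position_bp"] = np.nan
    marker_map = mp[["marker_id", "chromosome", "position_bp"]].copy()

    ids, rows = [], []
    m = len(marker_map)
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f".ped row for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}")
            ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.asarray(rows, dtype=object).reshape(len(ids), m, 2)

    dos = np.full((len(ids), m), np.nan)
    for j in range(m):
        col = alleles[:, j, :]
        called = col != "0"
        obs = sorted(set(col[called].ravel().tolist()))
        if len(obs) > 2:
            raise ValueError(f"marker {marker_map['marker_id'][j]} has >2 alleles: {obs}")
        counted = obs[-1] if obs else None
        both = called.all(axis=1)
        if counted is not None:
            dos[both, j] = (col[both] == counted).sum(axis=1)
    return (pd.DataFrame(dos, index=ids, columns=marker_map["marker_id"]),
            marker_map)


def write_plink(dosages: pd.DataFrame, marker_map: pd.DataFrame,
                ped_path, map_path, alleles: tuple[str, str] = ("A", "C")) -> None:
    """Write integer dosages as PLINK text .ped/.map (0 dosage -> A/A, 2 -> C/C)."""
    mp = marker_map.copy()
    mp["cm"] = 0
    mp["pos"] = mp["position_bp"].fillna(0).astype(int)
    mp[["chromosome", "marker_id", "cm", "pos"]].to_csv(
        map_path, sep=" ", header=False, index=False)
    a, b = alleles
    geno_map = {0: f"{a} {a}", 1: f"{a} {b}", 2: f"{b} {b}"}
    with open(ped_path, "w") as fh:
        for aid, row in dosages.iterrows():
            fields = [str(aid), str(aid), "0", "0", "0", "-9"]
            for v in row.to_numpy():
                if np.isnan(v):
                    fields.append("0 0")
                else:
                    fields.append(geno_map[int(round(v))])
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------- genes & terms


def read_bed(path) -> pd.DataFrame:
    """BED (0-based half-open) -> gene table with 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3],
                     names=["chromosome", "start0", "end0", "gene_id"],
                     dtype={"chromosome": str})
    return pd.DataFrame({
        "gene_id": df["gene_id"],
        "chromosome": df["chromosome"],
        "start_bp": df["start0"].astype(int) + 1,
        "end_bp": df["end0"].astype(int),
    })


def read_gff3(path, feature: str = "gene") -> pd.DataFrame:
    """Extract gene records (ID= or gene_id= attribute) from a GFF3 file."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature:
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gid = attrs.get("ID") or attrs.get("gene_id") or attrs.get("Name")
            if gid is None:
                continue
            rows.append({"gene_id": gid, "chromosome": f[0],
                         "start_bp": int(f[3]), "end_bp": int(f[4])})
    return pd.DataFrame(rows)


def read_terms(path) -> pd.DataFrame:
    """Gene -> ontology term annotation TSV: gene_id, term_id[, aspect]."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if "gene_id" not in cols:
        df = pd.read_csv(path, sep="\t", header=None)
        df.columns = ["gene_id", "term_id", "aspect"][: df.shape[1]]
    return df


# ---------------------------------------------------------------- windows & enrichment


def write_windows(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_windows(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chromosome": str})


def write_enrichment(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
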