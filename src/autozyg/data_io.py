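"""Genotype, genetic-map and group-label input/output.

The in-memory model is deliberately small: a :class:`GenotypePanel` holds
per-chromosome genotype codes for a set of diploid individuals, a
:class:`GeneticMap` holds a monotone physical(bp) to genetic(Morgan)
mapping, and group labels are a plain ``{individual: group}`` dict.

Coordinates are 1-based inclusive internally (VCF convention); BED output
converts to 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype codes
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

_GT_NAMES = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


@dataclass
class GenotypePanel:
    """Biallelic diploid genotypes for N individuals at S ordered sites.

    Parameters
    ----------
    individual_ids
        Sample labels, one per column of the genotype matrices.
    positions
        Per-chromosome strictly increasing physical positions (bp, 1-based).
    genotypes
        Per-chromosome ``(S, N)`` int8 matrices with codes
        ``HOM_REF``/``HET``/``HOM_ALT``/``MISSING``.
    population_of
        Optional individual -> population label map (used for frequency and
        LD estimation on multi-population panels).
    per_genotype_error
        Optional per-chromosome ``(S, N)`` matrices with a per-genotype
        error probability in (0, 1) (one minus the likelihood of the called
        genotype, for sequence data); NaN where missing.
    haplotypes
        Optional per-chromosome ``(S, 2N)`` allele matrices (0 = ref,
        1 = alt) when phase is known.  Column ``2i``/``2i+1`` are the two
        haplotypes of individual ``i``.  Phase is only consulted by the LD
        estimator; the likelihood model itself uses genotype codes.
    site_flags
        Optional per-chromosome dict of named per-site arrays (for example
        the simulator's de-novo flags); carried through site subsetting.
    """

    individual_ids: list[str]
    positions: dict[str, np.ndarray]
    genotypes: dict[str, np.ndarray]
    population_of: dict[str, str] = field(default_factory=dict)
    per_genotype_error: dict[str, np.ndarray] | None = None
    haplotypes: dict[str, np.ndarray] | None = None
    site_flags: dict[str, dict[str, np.ndarray]] | None = None

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_sites(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    def individual_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.individual_ids)}
        return np.asarray([lookup[s] for s in ids], dtype=np.int64)

    def individuals_of_population(self, population: str | None) -> np.ndarray:
        if population is None:
            return np.arange(self.n_individuals)
        keep = [i for i, s in enumerate(self.individual_ids)
                if self.population_of.get(s) == population]
        return np.asarray(keep, dtype=np.int64)

    def validate(self) -> None:
        for chrom, pos in self.positions.items():
            if len(pos) and np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
            g = self.genotypes[chrom]
            if g.shape != (len(pos), self.n_individuals):
                raise ValueError(f"genotype matrix shape mismatch on {chrom}")
            bad = ~np.isin(g, (HOM_REF, HET, HOM_ALT, MISSING))
            if bad.any():
                raise ValueError(f"invalid genotype codes on {chrom}")
            if self.per_genotype_error is not None:
                eps = self.per_genotype_error[chrom]
                ok = eps[g != MISSING]
                ok = ok[np.isfinite(ok)]
                if ok.size and (np.any(ok <= 0) or np.any(ok >= 1)):
                    raise ValueError("per-genotype error values must lie in (0,1)")

    def subset_sites(self, chrom: str, index: np.ndarray) -> "GenotypePanel":
        """Return a new panel keeping only ``index`` (sorted) on ``chrom``."""
        index = np.asarray(index)
        pos = {c: (p[index] if c == chrom else p.copy())
               for c, p in self.positions.items()}
        gen = {c: (g[index] if c == chrom else g.copy())
               for c, g in self.genotypes.items()}
        eps = None
        if self.per_genotype_error is not None:
            eps = {c: (e[index] if c == chrom else e.copy())
                   for c, e in self.per_genotype_error.items()}
        hap = None
        if self.haplotypes is not None:
            hap = {c: (h[index] if c == chrom else h.copy())
                   for c, h in self.haplotypes.items()}
        flags = None
        if self.site_flags is not None:
            flags = {c: ({k: (v[index] if c == chrom else v.copy())
                          for k, v in d.items()})
                     for c, d in self.site_flags.items()}
        return GenotypePanel(list(self.individual_ids), pos, gen,
                             dict(self.population_of), eps, hap, flags)


@dataclass
class GeneticMap:
    """Per-chromosome monotone physical(bp) <-> genetic(Morgan) mapping."""

    tables: dict[str, tuple[np.ndarray, np.ndarray]]  # bp, Morgans

    def validate(self) -> None:
        for chrom, (bp, g) in self.tables.items():
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"map bp not strictly increasing on {chrom}")
            if np.any(np.diff(g) < 0):
                raise ValueError(f"genetic positions decrease on {chrom}")

    def interpolate(self, chrom: str, positions) -> np.ndarray:
        """Linearly interpolated genetic positions (Morgans).

        Positions outside the tabulated range clamp to the terminal map
        values (``np.interp`` semantics); a tabulated point returns its
        tabulated value exactly.
        """
        bp, g = self.tables[chrom]
        positions = np.asarray(positions, dtype=np.float64)
        if positions.size and (positions.min() < bp[0] or positions.max() > bp[-1]):
            logger.info("positions outside map range on %s clamped to terminal values", chrom)
        return np.interp(positions, bp, g)


def interpolate_genetic_positions(gmap: GeneticMap, chrom: str, positions) -> np.ndarray:
    return gmap.interpolate(chrom, positions)


def read_genetic_map(path) -> GeneticMap:
    """Read a 3-column (chromosome, bp, cM) whitespace/comma table.

    The genetic coordinate is converted from cM to Morgans.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) < 3:
                raise ValueError(f"malformed map line: {line!r}")
            try:
                rows.append((parts[0], int(float(parts[1])), float(parts[2])))
            except ValueError:
                # tolerate a single header line
                if rows:
                    raise
    if not rows:
        raise ValueError("empty genetic map")
    df = pd.DataFrame(rows, columns=["chrom", "bp", "cm"])
    tables = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        bp = sub["bp"].to_numpy(dtype=np.int64)
        cm = sub["cm"].to_numpy(dtype=np.float64)
        order = np.argsort(bp)
        bp, cm = bp[order], cm[order]
        if np.any(np.diff(cm) < 0):
            raise ValueError(f"decreasing cM within chromosome {chrom}")
        tables[chrom] = (bp, cm / 100.0)
    gmap = GeneticMap(tables)
    gmap.validate()
    return gmap


def read_groups(path) -> dict[str, str]:
    """Read a 2-column (individual, group) whitespace/comma table."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\s]+", line)
            if len(parts) < 2:
                raise ValueError(f"malformed group line: {line!r}")
            groups[parts[0]] = parts[1]
    return groups


def validate_groups(panel: GenotypePanel, groups: dict[str, str]) -> None:
    known = set(panel.individual_ids)
    missing = [s for s in groups if s not in known]
    if missing:
        raise ValueError(f"labelled individuals absent from panel: {missing[:5]}")
    sizes = pd.Series(list(groups.values())).value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need at least two groups with >= 2 members each")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, region_filter=None, read_genotype_errors: bool = False) -> GenotypePanel:
    """Read biallelic SNVs from a VCF 4.x file into a :class:`GenotypePanel`.

    Multi-allelic and indel records are skipped (logged with a count).
    When ``read_genotype_errors`` is set, a per-genotype error is derived
    from PL (preferred) or GQ as ``eps = 1 - likelihood(called genotype)``,
    with the GQ convention ``eps = 10**(-GQ/10)``.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    code_of = np.array([HOM_REF, HET, MISSING, HOM_ALT], dtype=np.int8)

    positions: dict[str, list[int]] = {}
    genos: dict[str, list[np.ndarray]] = {}
    errs: dict[str, list[np.ndarray]] = {}
    haps: dict[str, list[np.ndarray]] = {}
    n_skipped = 0
    all_phased = True

    for v in vcf:
        chrom = v.CHROM
        if region_filter is not None and chrom not in region_filter:
            continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1 or v.ALT[0] not in "ACGT":
            n_skipped += 1
            continue
        plist = positions.setdefault(chrom, [])
        if plist and v.POS <= plist[-1]:
            raise ValueError(f"unsorted VCF input at {chrom}:{v.POS}")
        plist.append(v.POS)
        codes = code_of[np.asarray(v.gt_types)]
        genos.setdefault(chrom, []).append(codes)

        gts = v.genotypes  # [a0, a1, phased] per sample
        hap_row = np.full(2 * n, -1, dtype=np.int8)
        for i, gt in enumerate(gts):
            if len(gt) >= 3 and gt[2] and gt[0] >= 0 and gt[1] >= 0:
                hap_row[2 * i] = gt[0]
                hap_row[2 * i + 1] = gt[1]
            elif codes[i] != MISSING:
                all_phased = False
        haps.setdefault(chrom, []).append(hap_row)

        if read_genotype_errors:
            eps_row = np.full(n, np.nan)
            try:
                pl = v.format("PL")
            except KeyError:
                pl = None
            try:
                gq = v.format("GQ")
            except KeyError:
                gq = None
            if pl is not None and pl.shape[1] >= 3:
                lik = np.power(10.0, -np.clip(pl[:, :3], 0, None) / 10.0)
                tot = lik.sum(axis=1)
                for i in range(n):
                    c = codes[i]
                    if c != MISSING and tot[i] > 0:
                        eps_row[i] = 1.0 - lik[i, c] / tot[i]
            elif gq is not None:
                g = np.asarray(gq, dtype=float).reshape(-1)
                eps_row = np.power(10.0, -g / 10.0)
                eps_row[codes == MISSING] = np.nan
            errs.setdefault(chrom, []).append(eps_row)

    if n_skipped:
        logger.info("skipped %d non-biallelic-SNV records", n_skipped)
    if not positions:
        raise ValueError("no biallelic SNV records found")

    pos_arr = {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()}
    gen_arr = {c: np.vstack(g).astype(np.int8) for c, g in genos.items()}
    eps_arr = None
    if read_genotype_errors:
        eps_arr = {c: np.vstack(e) for c, e in errs.items()}
        # clamp to the open interval so downstream logs stay finite
        for e in eps_arr.values():
            np.clip(e, 1e-12, 1.0 - 1e-12, out=e)
    hap_arr = None
    if all_phased:
        hap_arr = {c: np.vstack(h).astype(np.int8) for c, h in haps.items()}
        for h in hap_arr.values():
            h[h > 1] = 1
    panel = GenotypePanel(samples, pos_arr, gen_arr,
                          per_genotype_error=eps_arr, haplotypes=hap_arr)
    panel.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    panel.validate()
    return panel


def write_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as an uncompressed VCF (alleles A/G placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in panel.chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.individual_ids) + "\n")
        for chrom in panel.chroms:
            pos = panel.positions[chrom]
            gen = panel.genotypes[chrom]
            hap = panel.haplotypes[chrom] if panel.haplotypes else None
            for s in range(len(pos)):
                if hap is not None:
                    cells = [f"{hap[s, 2*i]}|{hap[s, 2*i+1]}"
                             if gen[s, i] != MISSING else "./."
                             for i in range(panel.n_individuals)]
                else:
                    cells = [_GT_NAMES[int(g)] for g in gen[s]]
                fh.write(f"{chrom}\t{pos[s]}\t.\tA\tG\t.\tPASS\t.\tGT\t"
                         + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# ROA output
# ---------------------------------------------------------------------------

def write_roa_bed(roas, path) -> None:
    """Write one BED record per ROA per individual (0-based half-open).

    ``name`` is ``individual:classlabel`` and ``score`` the mean wLOD of
    the constituent windows.
    """
    df = roas.df
    with open(path, "w") as fh:
        for row in df.itertuples():
            name = f"{row.individual}:{row.class_label}"
            fh.write(f"{row.chrom}\t{row.start_bp - 1}\t{row.end_bp}\t"
                     f"{name}\t{row.mean_score:.4f}\n")


def write_roa_tsv(roas, path) -> None:
    cols = ["individual", "chrom", "start_bp", "end_bp", "length_bp",
            "start_cm", "end_cm", "length_cm", "n_windows", "mean_score",
            "class_label"]
    roas.df[cols].to_csv(path, sep="\t", index=False)
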