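"""Generate data/gene_models_synthetic.gff3 + data/gene_flags.tsv.

Gene spans approximate GRCh37 positions of the named genes; exon/CDS
structure is synthesized deterministically (these are synthetic stand-ins for
real transcript models). Flags: pLI, brain_expressed, is_ndd, is_gig,
is_lncrna.
"""

M = 1_000_000

# symbol: (chrom, start_mb, end_mb, pli, brain, ndd, gig, lnc)
GENES = {
    # --- genes named in the clinical-CNV fixture (category D anchors) ---
    "PSMD4":   ("1", 151.254, 151.264, 0.62, 1, 0, 0, 0),
    "MBD5":    ("2", 148.778, 149.271, 0.97, 1, 1, 0, 0),
    "NR4A2":   ("2", 157.180, 157.190, 0.91, 1, 0, 0, 0),
    "GPD2":    ("2", 157.292, 157.443, 0.01, 1, 0, 0, 0),
    "GULP1":   ("2", 182.010, 182.320, 0.12, 1, 0, 0, 0),
    "ADRA2C":  ("4", 3.766, 3.770, 0.30, 1, 0, 0, 0),
    "AP5Z1":   ("7", 4.815, 4.870, 0.00, 1, 0, 0, 0),
    "FOXK1":   ("7", 4.721, 4.811, 0.95, 1, 0, 0, 0),
    "FBXL18":  ("7", 5.520, 5.570, 0.57, 1, 0, 0, 0),
    "TNRC18":  ("7", 5.340, 5.460, 0.99, 1, 0, 0, 0),
    "AUTS2":   ("7", 69.063, 70.258, 0.99, 1, 1, 0, 0),
    "EN2":     ("7", 155.250, 155.258, 0.71, 1, 0, 0, 0),
    "RBM33":   ("7", 155.440, 155.570, 0.88, 1, 0, 0, 0),
    "CNPY1":   ("7", 155.700, 155.790, 0.05, 1, 0, 0, 0),
    "ZFAND4":  ("10", 45.850, 45.920, 0.02, 0, 0, 0, 0),
    "MARCH8":  ("10", 45.950, 46.050, 0.25, 1, 0, 0, 0),
    "USP7":    ("16", 8.986, 9.058, 1.00, 1, 0, 0, 0),
    "INPP5K":  ("17", 1.400, 1.422, 0.02, 1, 0, 0, 0),
    "PITPNA":  ("17", 1.422, 1.468, 0.91, 1, 0, 0, 0),
    "ACTG1":   ("17", 79.477, 79.480, 0.89, 1, 0, 0, 0),
    "CSNK1D":  ("17", 80.200, 80.231, 0.99, 1, 0, 0, 0),
    "COLEC12": ("18", 0.320, 0.500, 0.00, 0, 0, 0, 0),
    "YES1":    ("18", 0.721, 0.812, 0.76, 1, 0, 0, 0),
    "GRIN2D":  ("19", 48.898, 48.948, 0.82, 1, 0, 0, 0),
    "PDE9A":   ("21", 44.073, 44.195, 0.00, 1, 0, 0, 0),
    "UPB1":    ("22", 24.890, 24.922, 0.00, 0, 0, 0, 0),
    "ANOS1":   ("X", 8.500, 8.700, 0.93, 1, 1, 0, 0),
    "VCX3B":   ("X", 8.200, 8.210, 0.00, 0, 0, 0, 0),
    "SMC1A":   ("X", 53.401, 53.449, 1.00, 1, 1, 0, 0),
    # --- genes named in the fixture's inherited NDD-gene rows (category E) ---
    "SKI":     ("1", 2.160, 2.241, 0.96, 1, 1, 0, 0),
    "HFE2":    ("1", 145.413, 145.417, 0.00, 0, 1, 0, 0),
    "POGZ":    ("1", 151.375, 151.430, 1.00, 1, 1, 0, 0),
    "DISC1":   ("1", 231.763, 232.177, 0.01, 1, 1, 0, 0),
    "NRXN1":   ("2", 50.145, 51.259, 0.99, 1, 1, 0, 0),
    "DPP10":   ("2", 115.200, 116.600, 0.86, 1, 1, 0, 0),
    "CNTNAP5": ("2", 124.025, 125.920, 0.00, 1, 1, 0, 0),
    "CNTN4":   ("3", 2.120, 3.080, 0.74, 1, 1, 0, 0),
    "CNTN6":   ("3", 1.134, 1.445, 0.03, 1, 1, 0, 0),
    "SUMF1":   ("3", 4.100, 4.210, 0.01, 1, 1, 0, 0),
    "ITPR1":   ("3", 4.510, 4.890, 1.00, 1, 1, 0, 0),
    "GRM7":    ("3", 6.900, 7.780, 0.99, 1, 1, 0, 0),
    "NLGN1":   ("3", 173.116, 174.000, 0.98, 1, 1, 0, 0),
    "PAK2":    ("3", 196.466, 196.559, 1.00, 1, 1, 0, 0),
    "DLG1":    ("3", 196.769, 197.025, 1.00, 1, 1, 0, 0),
    "BDH1":    ("3", 197.232, 197.300, 0.00, 1, 0, 0, 0),
    "ANKRD17": ("4", 74.010, 74.124, 1.00, 1, 1, 0, 0),
    "COX18":   ("4", 73.920, 73.940, 0.00, 0, 0, 0, 0),
    "GRID2":   ("4", 93.300, 94.695, 0.92, 1, 1, 0, 0),
    "ANK2":    ("4", 113.200, 113.800, 1.00, 1, 1, 0, 0),
    "PITX2":   ("4", 111.538, 111.563, 0.90, 1, 0, 0, 0),
    "CTNND2":  ("5", 10.972, 11.904, 1.00, 1, 1, 0, 0),
    "MEF2C":   ("5", 88.014, 88.200, 1.00, 1, 1, 0, 0),
    "TMEM161B":("5", 87.450, 87.530, 0.26, 1, 0, 0, 0),
    "PTPRK":   ("6", 128.290, 128.840, 0.98, 1, 1, 0, 0),
    "LAMA2":   ("6", 129.204, 129.840, 0.00, 1, 1, 0, 0),
    "ARHGAP18":("6", 129.900, 130.100, 0.18, 1, 0, 0, 0),
    "ELN":     ("7", 73.442, 73.484, 0.21, 1, 1, 0, 0),
    "GRM8":    ("7", 126.078, 126.891, 0.96, 1, 1, 0, 0),
    "CNTNAP2": ("7", 145.910, 147.800, 0.99, 1, 1, 0, 0),
    "KMT2C":   ("7", 151.832, 152.133, 1.00, 1, 1, 0, 0),
    "DPP6":    ("7", 153.584, 154.686, 0.99, 1, 1, 0, 0),
    "PAXIP1":  ("7", 154.735, 154.795, 0.98, 1, 0, 0, 0),
    "HTR5A":   ("7", 154.862, 154.880, 0.51, 1, 0, 0, 0),
    "PTPRN2":  ("7", 157.332, 158.380, 0.83, 1, 1, 0, 0),
    "ESYT2":   ("7", 158.500, 158.620, 0.13, 1, 0, 0, 0),
    "NCAPG2":  ("7", 158.630, 158.700, 0.00, 1, 0, 0, 0),
    "DLGAP2":  ("8", 1.440, 1.657, 0.95, 1, 1, 0, 0),
    "CLN8":    ("8", 1.703, 1.734, 0.02, 1, 0, 0, 0),
    "ARHGEF10":("8", 1.772, 1.906, 0.00, 1, 0, 0, 0),
    "MCPH1":   ("8", 6.170, 6.420, 0.00, 1, 1, 0, 0),
    "PTPRD":   ("9", 8.400, 9.000, 1.00, 1, 1, 0, 0),
    "ASTN2":   ("9", 119.187, 120.177, 0.95, 1, 1, 0, 0),
    "TRIM32":  ("9", 119.449, 119.464, 0.01, 1, 0, 0, 0),
    "PAPPA":   ("9", 118.810, 119.060, 0.27, 1, 0, 0, 0),
    "PCDH15":  ("10", 55.562, 57.588, 0.00, 1, 1, 0, 0),
    "CTNNA3":  ("10", 67.672, 69.456, 0.00, 1, 1, 0, 0),
    "POLL":    ("10", 103.310, 103.320, 0.01, 0, 1, 0, 0),
    "BTRC":    ("10", 103.113, 103.317, 0.99, 1, 0, 0, 0),
    "DPCD":    ("10", 103.340, 103.370, 0.00, 0, 0, 0, 0),
    "DRD4":    ("11", 0.637, 0.641, 0.01, 1, 1, 0, 0),
    "PAX6":    ("11", 31.790, 31.818, 1.00, 1, 1, 0, 0),
    "ELP4":    ("11", 31.531, 31.790, 0.26, 1, 0, 0, 0),
    "SHANK2":  ("11", 69.992, 70.446, 1.00, 1, 1, 0, 0),
    "DLG2":    ("11", 83.166, 85.339, 0.99, 1, 1, 0, 0),
    "CNTN5":   ("11", 98.891, 100.230, 0.21, 1, 1, 0, 0),
    "KMT2A":   ("11", 118.307, 118.397, 1.00, 1, 1, 0, 0),
    "CACNA1C": ("12", 2.032, 2.802, 1.00, 1, 1, 0, 0),
    "PCDH9":   ("13", 66.877, 67.804, 0.93, 1, 1, 0, 0),
    "CHD8":    ("14", 21.853, 21.941, 1.00, 1, 1, 0, 0),
    "NRXN3":   ("14", 79.434, 80.334, 0.98, 1, 1, 0, 0),
    "APBA2":   ("15", 29.130, 29.320, 0.89, 1, 1, 0, 0),
    "CHRNA7":  ("15", 32.322, 32.462, 0.47, 1, 1, 0, 0),
    "RBFOX1":  ("16", 6.019, 7.713, 0.99, 1, 1, 0, 0),
    "ATP2A1":  ("16", 28.889, 28.915, 0.02, 1, 1, 0, 0),
    "ATP2C2":  ("16", 84.402, 84.497, 0.00, 1, 1, 0, 0),
    "TLDC1":   ("16", 84.500, 84.540, 0.10, 1, 0, 0, 0),
    "ANKRD11": ("16", 89.334, 89.557, 1.00, 1, 1, 0, 0),
    "NF1":     ("17", 29.421, 29.704, 1.00, 1, 1, 0, 0),
    "DLGAP1":  ("18", 3.496, 3.880, 0.97, 1, 1, 0, 0),
    "CDH7":    ("18", 63.999, 64.156, 0.03, 1, 1, 0, 0),
    "CDH19":   ("18", 64.170, 64.272, 0.01, 1, 0, 0, 0),
    "MACROD2": ("20", 13.976, 16.033, 0.01, 1, 1, 0, 0),
    "PTPRT":   ("20", 40.701, 41.819, 0.99, 1, 1, 0, 0),
    "SNAP29":  ("22", 21.213, 21.246, 0.26, 1, 1, 0, 0),
    "LZTR1":   ("22", 21.333, 21.353, 0.97, 1, 0, 0, 0),
    "CACNA1I": ("22", 39.967, 40.089, 0.99, 1, 1, 0, 0),
    "ARSE":    ("X", 2.852, 2.882, 0.04, 0, 1, 0, 0),
    "PTCHD1-AS":("X", 22.850, 23.000, None, 1, 1, 0, 1),
    "IL1RAPL1":("X", 28.605, 29.974, 0.96, 1, 1, 0, 0),
    "DMD":     ("X", 31.137, 33.357, 0.91, 1, 1, 0, 0),
    "TAB3":    ("X", 30.840, 30.890, 0.90, 1, 0, 0, 0),
    "FTHL17":  ("X", 31.088, 31.091, 0.00, 0, 0, 0, 0),
    "RAB38B":  ("X", 153.020, 153.095, 0.55, 1, 1, 0, 0),
    # --- genes inside recurrent-locus / large-CNV regions (de novo gene hits) ---
    "FAM19A1": ("3", 68.060, 68.620, 0.37, 1, 0, 0, 0),
    "FOXP2":   ("7", 114.055, 114.660, 1.00, 1, 1, 0, 0),
    "SALL1":   ("16", 51.170, 51.230, 0.99, 1, 0, 0, 0),
    "CHAT":    ("10", 50.817, 50.900, 0.00, 1, 0, 0, 0),
    "NDE1":    ("16", 15.644, 15.727, 0.25, 1, 0, 0, 0),
    "TBX1":    ("22", 19.744, 19.772, 0.33, 1, 0, 0, 0),
    "SRY":     ("Y", 2.654, 2.656, 0.00, 0, 0, 0, 0),
    "RBMY1A1": ("Y", 21.511, 21.550, 0.00, 0, 0, 0, 0),
    # --- genomic-instability (DNA repair/replication) genes ---
    "PALB2":   ("16", 23.614, 23.652, 0.00, 0, 0, 1, 0),
    "EXO1":    ("1", 242.011, 242.075, 0.00, 0, 0, 1, 0),
    "RAD1":    ("5", 34.905, 34.920, 0.01, 0, 0, 1, 0),
    "MBD4":    ("3", 129.149, 129.159, 0.00, 0, 0, 1, 0),
}


def exon_layout(start, end):
    """Deterministic exon structure: 2-8 exons, exon 1 is UTR-only."""
    span = end - start
    if span < 5000:
        return [(start, end)], [(start, end)]  # single-exon, fully coding
    n = max(2, min(4, span // 300_000 + 2))
    exon_len = max(150, min(2000, span // (4 * n)))
    gap = (span - n * exon_len) // (n - 1) if n > 1 else 0
    exons = []
    pos = start
    for i in range(int(n)):
        exons.append((pos, pos + exon_len))
        pos += exon_len + gap
    exons[-1] = (min(exons[-1][0], end - exon_len), end)
    cds = exons[1:]  # first exon is 5' UTR
    return exons, cds


def main():
    gff = ["##gff-version 3",
           "# Synthetic GRCh37 gene models: gene spans approximate the named",
           "# genes' true loci; transcript/exon/CDS structure is synthesized.",
           ]
    flag_rows = ["gene_id\tsymbol\tpli\tbrain_expressed\tis_ndd\tis_gig\tis_lncrna"]
    for sym in sorted(GENES, key=lambda s: (GENES[s][0], GENES[s][1])):
        chrom, s_mb, e_mb, pli, brain, ndd, gig, lnc = GENES[sym]
        start, end = int(round(s_mb * M)), int(round(e_mb * M))
        assert end > start, sym
        gid = sym
        tid = f"{sym}-t1"
        gtype = "lncRNA_gene" if lnc else "gene"
        ttype = "lnc_RNA" if lnc else "mRNA"
        gff.append(f"{chrom}\tsynthetic\tgene\t{start+1}\t{end}\t.\t+\t.\t"
                   f"ID={gid};Name={sym};biotype={'lncRNA' if lnc else 'protein_coding'}")
        gff.append(f"{chrom}\tsynthetic\t{ttype}\t{start+1}\t{end}\t.\t+\t.\t"
                   f"ID={tid};Parent={gid}")
        exons, cds = exon_layout(start, end)
        for i, (es, ee) in enumerate(exons, 1):
            gff.append(f"{chrom}\tsynthetic\texon\t{es+1}\t{ee}\t.\t+\t.\t"
                       f"ID={tid}-e{i};Parent={tid}")
        if not lnc:
            for i, (cs, ce) in enumerate(cds, 1):
                gff.append(f"{chrom}\tsynthetic\tCDS\t{cs+1}\t{ce}\t.\t+\t0\t"
                           f"ID={tid}-cds{i};Parent={tid}")
        pli_s = "" if pli is None else f"{pli:.2f}"
        flag_rows.append(f"{gid}\t{sym}\t{pli_s}\t{brain}\t{ndd}\t{gig}\t{lnc}")
    with open("src/xnddcnv/data/gene_models_synthetic.gff3", "w") as fh:
        fh.write("\n".join(gff) + "\n")
    with open("src/xnddcnv/data/gene_flags.tsv", "w") as fh:
        fh.write("\n".join(flag_rows) + "\n")
    print(f"{len(GENES)} genes")


if __name__ == "__main__":
    main()
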