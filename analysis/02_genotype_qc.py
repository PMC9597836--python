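#!/usr/bin/env python
"""Quality control of the simulated SNP-array genotypes.

Applies the chip-data filters (unplaced/X markers out, SNP missing-call
fraction >= 5% out, individual call rate < 95% out) to each herd and
writes the filtered binary fileset plus a QC report.
"""

from pathlib import Path

from rohbridge.plinkio import qc_filter, read_plink_binary, write_plink_binary

ROOT = Path(__file__).resolve().parents[1]


def main():
    for species in ("goat", "sheep"):
        d = ROOT / "results" / "sim" / species
        ds = read_plink_binary(d / "herd.bed", d / "herd.bim", d / "herd.fam",
                               species=species)
        out_ds, report = qc_filter(ds)
        write_plink_binary(out_ds, d / "qc.bed", d / "qc.bim", d / "qc.fam")
        (d / "qc_report.json").write_text(report.to_json())
        (d / "qc_report.txt").write_text(str(report) + "\n")
        print(f"{species}: {report.n_snps_in} -> {report.n_snps_out} SNPs, "
              f"{report.n_ind_in} -> {report.n_ind_out} individuals retained")


if __name__ == "__main__":
    main()
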