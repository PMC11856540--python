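# Published mitogenome records

The acceptance checks in `tests/test_acceptance.py` that compare against
published gene annotations need the following GenBank flat files in this
directory (named `<accession>.gb`):

| Accession    | Species                  | Used for                          |
|--------------|--------------------------|-----------------------------------|
| KF658070.1   | Diabrotica virgifera     | COX3 length (789 bp)              |
| OU815794.1   | Phaedon cochleariae      | ND5 length (1722 bp)              |
| KX943506.1   | Phyllotreta cruciferae   | ND5 length (1668 bp); ATP8 pair   |
| NC_045901.1  | Phyllotreta striolata    | ATP8 cross-species identity       |

Fetch them with NCBI E-utilities, e.g.:

```bash
for acc in KF658070.1 OU815794.1 KX943506.1 NC_045901.1; do
  curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nucleotide&id=${acc}&rettype=gb&retmode=text" \
    > "${acc}.gb"
done
```

Without these files the corresponding tests fail with a message pointing
here; every other test runs on synthetic data generated at test time.
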