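# Local structure data

Place PDB-format coordinate files here as `<id>.pdb` (lower- or
upper-case), e.g. `1vgm.pdb` and `1vgp.pdb` for the two *Sulfolobus
tokodaii* citrate-synthase isozymes.  With network access you can fetch
them with:

```
saltnet fetch 1VGM
saltnet fetch 1VGP
```

The structure-dependent regression checks in `tests/test_acceptance.py`
and the published-comparison section of `scripts/acceptance.py` run on
these files when present; everything else in the package is exercised on
synthetic fixtures and needs no downloads.
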