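# Crystal-structure inputs

The crystal-geometry benchmarks (`oligorot.crystal`, acceptance targets
t1–t6) read deposited PDB entries from this directory:

| file | content |
|---|---|
| `1F9N.pdb` | intact apo hexamer, chains A–F |
| `2P5M.pdb` | holo C-terminal domain, deposited as a trimer |
| `2P5M_assembly.json` | rigid transforms (JSON list of `{rotation, translation, chain_map}`) building the 2P5M hexamer from the deposited trimer |
| `2P5L.pdb` | two N-terminal domains bound to palindromic DNA |
| `3FHZ.pdb` | divergent-family holo hexamer |
| `3BUE.pdb` | divergent-family apo C-domain hexamer |

Download from RCSB, e.g.

```bash
for id in 1F9N 2P5M 2P5L 3FHZ 3BUE; do
  curl -sf -o $id.pdb https://files.rcsb.org/download/$id.pdb
done
```

The build environment for this repository had no network route to
`files.rcsb.org`, so the files are not bundled; everything that does not
need them runs offline on synthetic data.
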