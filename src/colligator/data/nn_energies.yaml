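# Nearest-neighbour free-energy parameters for perfect RNA stem-loops,
# 37 C, kcal/mol. Watson-Crick stack values follow the standard Turner
# 2004 set; G-U wobble stacks and tetraloop bonuses are approximate.
# Stack keys read "XY/ZW" = 5'-X Y-3' over 3'-Z W-5' (X pairs Z as the
# outer pair, Y pairs W as the inner pair); the lookup also tries the
# 180-degree-rotated key, so only one orientation is listed.
version: colligator-nn-1
stack:
  # Watson-Crick on Watson-Crick
  AA/UU: -0.93
  AU/UA: -1.10
  UA/AU: -1.33
  CU/GA: -2.08
  CA/GU: -2.11
  GU/CA: -2.24
  GA/CU: -2.35
  CG/GC: -2.36
  GG/CC: -3.26
  GC/CG: -3.42
  # Watson-Crick outer, G-U wobble inner (approximate)
  AG/UU: -1.40
  AU/UG: -1.30
  UG/AU: -1.40
  UU/AG: -1.20
  CG/GU: -2.10
  CU/GG: -1.90
  GG/CU: -2.20
  GU/CG: -2.50
  # wobble on wobble (approximate)
  GG/UU: -0.40
  GU/UG: -0.50
  UG/GU: 0.50
loop_init:
  3: 5.4
  4: 5.6
  5: 5.7
  6: 5.4
  7: 6.0
  8: 5.5
  9: 6.4
# beyond size 9: loop_init(9) + 1.75 * RT * ln(n/9), RT = 0.616
tetraloop_bonus:
  # key = 5' closing base + loop + 3' closing base
  CUUCGG: -3.0
  GUUCGC: -2.5
  CGAAAG: -2.5
  GGAAAC: -2.5
  CGCAAG: -2.0
  CUACGG: -2.0
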