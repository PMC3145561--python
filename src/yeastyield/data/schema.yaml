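# Corpus file dialects. Both are tab- or comma-separated text with a
# mandatory header row; the delimiter is sniffed from the header line.
dialects:
  preencoded:
    description: >
      Columns exactly as the curated literature training table. Step
      columns accept the dual notation "a(b)" (substrate-side count a,
      intermediate-side count b) on rows where an intermediate was fed
      (INT_C2 = 1). Category columns are 0/1 dummies; OVE_C2 and OVE_C3
      are mutually exclusive.
    columns:
      - {name: Reference, type: string}
      - {name: Product, type: string}
      - {name: Yield, type: float, constraint: "0 < Yield <= 1 (C-mol/C-mol)"}
      - {name: PrimaryStep, type: "count or a(b)"}
      - {name: SecondStep, type: "count or a(b)"}
      - {name: OVE_C2, type: "0/1"}
      - {name: OVE_C3, type: "0/1"}
      - {name: KNO_C2, type: "0/1"}
      - {name: NUT_C2, type: "0/1"}
      - {name: INT_C2, type: "0/1"}
      - {name: CUL_C2, type: "0/1"}
      - {name: OXY_C2, type: "0/1"}
  raw:
    description: >
      Category tokens C1/C2/C3 instead of dummies; intermediate-side step
      counts in their own columns, empty when no intermediate was fed.
    columns:
      - {name: reference, type: string}
      - {name: product, type: string}
      - {name: yield, type: float, constraint: "0 < yield <= 1"}
      - {name: pri_sub, type: count}
      - {name: pri_int, type: "count or empty"}
      - {name: sec_sub, type: count}
      - {name: sec_int, type: "count or empty"}
      - {name: OVE, type: "C1|C2|C3"}
      - {name: KNO, type: "C1|C2"}
      - {name: NUT, type: "C1|C2"}
      - {name: INT, type: "C1|C2"}
      - {name: CUL, type: "C1|C2"}
      - {name: OXY, type: "C1|C2"}
notes:
  - Yields originally printed in scientific notation are stored as
    e-notation decimal floats (e.g. 8.8e-5).
  - The n-Butanol secondary-step entry typeset in bold in the source
    table is read as the number 6.
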