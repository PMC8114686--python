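# Phase markers of the mammalian cell cycle (RB/E2F pathway map).
# Marker entities use the textual grammar: ":" separates complex subunits,
# "(...)" carries state variables, "value@site" a modification at a residue.
name: cell cycle
phases:
  - name: early G1
    markers:
      - {entity: "CCND1:CDK6(P@Thr):CDKN1B", compartment: Nucleoplasm}
      - {entity: "pRB:E2F1:DP1:SWI:SNF:HDAC1", compartment: Nucleoplasm}
      - {entity: "SWI:SNF:HDAC1:SUV39H1:pRB:E2F1:DP1", compartment: Nucleoplasm}
      - {entity: "CCND1:CDK4(P@Thr172):CDKN1B", compartment: Nucleoplasm}
      - {entity: "pRB:E2F1:DP1:SWI:SNF:HDAC1:SUV39H1:HP1gamma", compartment: Nucleoplasm}
  - name: late G1
    markers:
      - {entity: "pRB(P):E2F1:DP1:SWI:SNF:HDAC1", compartment: Nucleoplasm}
      - {entity: "pRB(P|P):E2F1:DP1:SWI:SNF", compartment: Nucleoplasm}
  - name: early S
    markers:
      - {entity: "CCNE1:CDK2(P@Thr160)", compartment: Nucleoplasm}
  - name: late S
    markers:
      - {entity: "CCNA2:CDK2(P@Thr160)", compartment: Nucleoplasm}
  - name: G2
    markers:
      - {entity: "CCNB1:CDK1(P@Tyr15)", compartment: Cytoplasm}
      - {entity: "CCNB1:CDK1(P@Tyr15|P@Thr14)", compartment: Cytoplasm}
      - {entity: "CCNB1:CDK1", compartment: Cytoplasm}
      - {entity: "CCNB1:CDK1(P@Thr14)", compartment: Cytoplasm}
  - name: M
    markers:
      - {entity: "CDC25(P)", compartment: Nucleoplasm}
      - {entity: "WEE1(P@Ser53)", compartment: Nucleoplasm}
      - {entity: "CCNB1:CDK1(P@Thr161)", compartment: Nucleoplasm}
      - {entity: "CDC20(P)", compartment: Nucleoplasm}
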