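# Phase markers of the circadian clock: activity peaks of core clock
# entities, in cyclic order.
name: circadian clock
phases:
  - name: RORG
    markers:
      - {entity: "RORG", compartment: Nucleoplasm}
  - name: SIRT1
    markers:
      - {entity: "SIRT1", compartment: Nucleoplasm}
  - name: ARNTL-CLOCK
    markers:
      - {entity: "ARNTL(Ac@L538|P@S90):CLOCK(ADPr):CSNK2A", compartment: Nucleoplasm}
  - name: PER-CRY
    markers:
      - {entity: "PER1:CRY1:CRY2:ARNTL(Ac@L538|P@S90):CLOCK(ADPr):PER2(Ac):CSNK1D:CSNK1E", compartment: Nucleoplasm}
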