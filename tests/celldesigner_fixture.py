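"""Synthetic CellDesigner extended-SBML document for reader tests.

Hand-written stand-in exercising the supported subset: species classes,
modification residues, complexes via included species, reaction types,
modifier types, and MIRIAM annotations.  It is not derived from any
published map.
"""

SYNTHETIC_CELLDESIGNER_XML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4"
      xmlns:celldesigner="http://www.sbml.org/2001/ns/celldesigner"
      level="2" version="4">
  <model id="toy_model" name="toy model">
    <annotation>
      <celldesigner:extension>
        <celldesigner:modelVersion>4.0</celldesigner:modelVersion>
        <celldesigner:listOfIncludedSpecies>
          <celldesigner:species id="s_cA" name="CA">
            <celldesigner:notes/>
            <celldesigner:annotation>
              <celldesigner:complexSpecies>s4</celldesigner:complexSpecies>
              <celldesigner:speciesIdentity>
                <celldesigner:class>PROTEIN</celldesigner:class>
                <celldesigner:proteinReference>pr1</celldesigner:proteinReference>
                <celldesigner:state>
                  <celldesigner:listOfModifications>
                    <celldesigner:modification residue="rs1" state="phosphorylated"/>
                  </celldesigner:listOfModifications>
                </celldesigner:state>
              </celldesigner:speciesIdentity>
            </celldesigner:annotation>
          </celldesigner:species>
          <celldesigner:species id="s_cB" name="CB">
            <celldesigner:annotation>
              <celldesigner:complexSpecies>s4</celldesigner:complexSpecies>
              <celldesigner:speciesIdentity>
                <celldesigner:class>PROTEIN</celldesigner:class>
                <celldesigner:proteinReference>pr2</celldesigner:proteinReference>
              </celldesigner:speciesIdentity>
            </celldesigner:annotation>
          </celldesigner:species>
        </celldesigner:listOfIncludedSpecies>
        <celldesigner:listOfProteins>
          <celldesigner:protein id="pr1" name="CA" type="GENERIC">
            <celldesigner:listOfModificationResidues>
              <celldesigner:modificationResidue id="rs1" name="Thr172"/>
            </celldesigner:listOfModificationResidues>
          </celldesigner:protein>
          <celldesigner:protein id="pr2" name="CB" type="GENERIC"/>
          <celldesigner:protein id="pr3" name="KIN" type="GENERIC">
            <celldesigner:listOfModificationResidues>
              <celldesigner:modificationResidue id="rs2" name="Ser53"/>
            </celldesigner:listOfModificationResidues>
          </celldesigner:protein>
        </celldesigner:listOfProteins>
      </celldesigner:extension>
    </annotation>
    <listOfCompartments>
      <compartment id="c1" name="cytoplasm" size="1"/>
      <compartment id="c2" name="nucleoplasm" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="s1" name="KIN" compartment="c1">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>PROTEIN</celldesigner:class>
              <celldesigner:proteinReference>pr3</celldesigner:proteinReference>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
          <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                   xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">
            <rdf:Description rdf:about="#s1">
              <bqbiol:is>
                <rdf:Bag>
                  <rdf:li rdf:resource="urn:miriam:uniprot:P00000"/>
                  <rdf:li rdf:resource="http://identifiers.org/ncbigene/12345"/>
                </rdf:Bag>
              </bqbiol:is>
            </rdf:Description>
          </rdf:RDF>
        </annotation>
      </species>
      <species id="s2" name="KIN" compartment="c2">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>PROTEIN</celldesigner:class>
              <celldesigner:proteinReference>pr3</celldesigner:proteinReference>
              <celldesigner:state>
                <celldesigner:listOfModifications>
                  <celldesigner:modification residue="rs2" state="phosphorylated"/>
                </celldesigner:listOfModifications>
              </celldesigner:state>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
      <species id="s3" name="atp" compartment="c1">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>SIMPLE_MOLECULE</celldesigner:class>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
      <species id="s4" name="CA:CB" compartment="c2">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>COMPLEX</celldesigner:class>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
      <species id="s5" name="Kin gene" compartment="c2">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>GENE</celldesigner:class>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
      <species id="s6" name="sink" compartment="c1">
        <annotation>
          <celldesigner:extension>
            <celldesigner:speciesIdentity>
              <celldesigner:class>DEGRADED</celldesigner:class>
            </celldesigner:speciesIdentity>
          </celldesigner:extension>
        </annotation>
      </species>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="re1" reversible="false">
        <annotation>
          <celldesigner:extension>
            <celldesigner:reactionType>STATE_TRANSITION</celldesigner:reactionType>
            <celldesigner:listOfModification>
              <celldesigner:modification type="CATALYSIS" modifiers="s3"
                aliases="sa3" targetLineIndex="-1,0"/>
            </celldesigner:listOfModification>
          </celldesigner:extension>
        </annotation>
        <listOfReactants>
          <speciesReference species="s1"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="s2"/>
        </listOfProducts>
        <listOfModifiers>
          <modifierSpeciesReference species="s3"/>
        </listOfModifiers>
      </reaction>
      <reaction id="re2" reversible="false">
        <annotation>
          <celldesigner:extension>
            <celldesigner:reactionType>HETERODIMER_ASSOCIATION</celldesigner:reactionType>
          </celldesigner:extension>
        </annotation>
        <listOfReactants>
          <speciesReference species="s2"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="s4"/>
        </listOfProducts>
      </reaction>
      <reaction id="re3" reversible="false">
        <annotation>
          <celldesigner:extension>
            <celldesigner:reactionType>TRANSCRIPTION</celldesigner:reactionType>
            <celldesigner:listOfModification>
              <celldesigner:modification type="TRIGGER" modifiers="s4"/>
            </celldesigner:listOfModification>
          </celldesigner:extension>
        </annotation>
        <listOfReactants>
          <speciesReference species="s5"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="s5"/>
        </listOfProducts>
        <listOfModifiers>
          <modifierSpeciesReference species="s4"/>
        </listOfModifiers>
      </reaction>
      <reaction id="re4" reversible="false">
        <annotation>
          <celldesigner:extension>
            <celldesigner:reactionType>DEGRADATION</celldesigner:reactionType>
          </celldesigner:extension>
        </annotation>
        <listOfReactants>
          <speciesReference species="s1"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="s6"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

PLAIN_SBML_XML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="plain">
    <listOfSpecies>
      <species id="s1" name="X" compartment="c1"/>
    </listOfSpecies>
  </model>
</sbml>
"""
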