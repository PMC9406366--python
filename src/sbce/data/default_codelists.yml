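# Synthetic demonstration code lists for the four SBCE criteria.
#
# These codes are NOT clinical code lists. They imitate the *shape* of the
# coding systems found in linked administrative data (an ICD-10-like
# diagnosis hierarchy, intervention-style procedure codes, drug and
# radiotherapy identifiers) so that the rule engine, the simulator and the
# test suite have a concrete, self-consistent configuration to run against.
# A production deployment replaces this file with clinically curated lists.
provenance: "sbce packaged synthetic defaults (non-clinical)"
criteria:
  death_breast_cancer:
    cause_of_death:
      code_system: ICD10-SYN
      match_mode: prefix
      codes:
        - C50
  procedure_diagnosis:
    inpatient_procedure:
      code_system: CCI-SYN
      match_mode: exact
      codes:
        - 1YM87   # partial breast excision (synthetic)
        - 1YM89   # total mastectomy (synthetic)
        - 1YM91   # mastectomy with node dissection (synthetic)
        - 1YK87   # axillary node excision (synthetic)
      diagnosis:
        code_system: ICD10-SYN
        match_mode: prefix
        codes:
          - C50   # malignant neoplasm of breast (synthetic)
          - C79   # secondary malignant neoplasm (synthetic)
    ambulatory_procedure:
      code_system: CCI-SYN
      match_mode: exact
      codes:
        - 1YM87
        - 1YM89
        - 1YK87
      diagnosis:
        code_system: ICD10-SYN
        match_mode: prefix
        codes:
          - C50
          - C79
  systemic_treatment:
    systemic_therapy:
      code_system: DIN-SYN
      match_mode: exact
      codes:
        - SYS001  # anthracycline course (synthetic)
        - SYS002  # taxane course (synthetic)
        - SYS003  # anti-HER2 agent (synthetic)
        - SYS004  # metastatic-line agent (synthetic)
  radiotherapy:
    radiotherapy:
      code_system: RT-SYN
      match_mode: exact
      codes:
        - RT100   # breast/chest-wall course (synthetic)
        - RT101   # nodal irradiation (synthetic)
        - RT102   # palliative course, bone (synthetic)
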