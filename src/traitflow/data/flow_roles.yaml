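note: Default flow-role configuration for the anaerobic/aerobic polyphosphate-accumulating organism model.
  The function_ids are PLACEHOLDERS (K9MMNN, MM = module id); supply real KO sets for production use.
modules:
- module_id: 1
  name: acetate uptake
  function_ids: [K90101, K90102, K90103, K90104, K90105, K90106, K90107, K90108]
  roles:
    AN: {carbon: 1-pro, energy: 1-con}
    AE: {}
- module_id: 2
  name: PHA
  function_ids: [K90201, K90202, K90203, K90204, K90205, K90206, K90207, K90208]
  roles:
    AN: {carbon: 1-con, electron: 1-con}
    AE: {carbon: 1-pro, electron: 2-pro}
- module_id: 3
  name: LCFA
  function_ids: [K90301, K90302, K90303, K90304, K90305, K90306, K90307, K90308]
  roles:
    AN: {carbon: inter, electron: 2-pro}
    AE: {carbon: 2-con}
- module_id: 4
  name: AA
  function_ids: [K90401, K90402, K90403, K90404, K90405, K90406, K90407, K90408]
  roles:
    AN: {carbon: 2-pro}
    AE: {carbon: 2-con}
- module_id: 5
  name: glutamate/N
  function_ids: [K90501, K90502, K90503, K90504, K90505, K90506, K90507, K90508]
  roles:
    AN: {carbon: 2-pro}
    AE: {}
- module_id: 6
  name: Gly
  function_ids: [K90601, K90602, K90603, K90604, K90605, K90606, K90607, K90608]
  roles:
    AN: {carbon: 2-pro, electron: 1-pro}
    AE: {carbon: 2-con, electron: 2-con}
- module_id: 7
  name: complete TCA
  function_ids: [K90701, K90702, K90703, K90704, K90705, K90706, K90707, K90708]
  roles:
    AN: {carbon: 2-con, electron: 2-pro}
    AE: {carbon: 1-con, electron: 1-pro}
- module_id: 8
  name: split TCA (reductive branch)
  function_ids: [K90801, K90802, K90803, K90804, K90805, K90806, K90807, K90808]
  roles:
    AN: {electron: 2-pro}
    AE: {}
- module_id: 9
  name: split TCA (oxidative branch)
  function_ids: [K90901, K90902, K90903, K90904, K90905, K90906, K90907, K90908]
  roles:
    AN: {}
    AE: {}
- module_id: 10
  name: partial TCA
  function_ids: [K91001, K91002, K91003, K91004, K91005, K91006, K91007, K91008]
  roles:
    AN: {electron: 2-pro}
    AE: {carbon: 2-con, electron: 2-pro}
- module_id: 11
  name: denitrification/N reduction
  function_ids: [K91101, K91102, K91103, K91104, K91105, K91106, K91107, K91108]
  roles:
    AN: {electron: 2-con}
    AE: {}
- module_id: 12
  name: hydrogenases
  function_ids: [K91201, K91202, K91203, K91204, K91205, K91206, K91207, K91208]
  roles:
    AN: {electron: 2-con}
    AE: {}
- module_id: 13
  name: PolyP
  function_ids: [K91301, K91302, K91303, K91304, K91305, K91306, K91307, K91308]
  roles:
    AN: {energy: 1-pro}
    AE: {energy: 1-con}
- module_id: 14
  name: P transporters (pst/pit)
  function_ids: [K91401, K91402, K91403, K91404, K91405, K91406, K91407, K91408]
  roles:
    AN: {}
    AE: {}
- module_id: 15
  name: ETP
  function_ids: [K91501, K91502, K91503, K91504, K91505, K91506, K91507, K91508]
  roles:
    AN: {electron: 2-con}
    AE: {electron: 1-con, energy: 1-pro}
- module_id: 16
  name: PL
  function_ids: [K91601, K91602, K91603, K91604, K91605, K91606, K91607, K91608]
  roles:
    AN: {carbon: 2-con}
    AE: {carbon: 2-con}
- module_id: 17
  name: EPS
  function_ids: [K91701, K91702, K91703, K91704, K91705, K91706, K91707, K91708]
  roles:
    AN: {}
    AE: {carbon: 2-con}
- module_id: 18
  name: acetate to pyruvate
  function_ids: [K91801, K91802, K91803, K91804, K91805, K91806, K91807, K91808]
  roles:
    AN: {}
    AE: {}
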