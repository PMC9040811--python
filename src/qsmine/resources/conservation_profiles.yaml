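# qsmine packaged conservation profiles and motif definitions.
#
# Key-residue positions are 1-based coordinates on the profile's reference
# sequence. The reference sequences here are SYNTHETIC stand-ins, generated
# deterministically so that every key position and motif anchor is satisfied;
# real reference proteins for these families are not redistributed with the
# package. Replace `reference_seq` with a curated family reference to run the
# checks against real numbering.
version: 1
profiles:
  luxi:
    role: LuxI
    reference_id: synthetic_luxi_reference
    reference_seq: >-
      HWQIDSINPGIWSVDICYQFTTRQDLFASVRNWIKILQLHPECDHCDGFTVTLQQLKYLT
      IFVNNYCRFITLEMSWCRSIFFECGLPFGCLCHFAQAEIEYPRYRLKSAAAPKYPAWWGE
      DQCAHCFDVWESCQWPFGWMCLMYVLGRWIDWFVWYSFHVHLQMTMPCPVKPGDKRHDGI
      LQDLSCWPMILIQEREWYEPTNPSCIAEMP
    key_positions:
      - {position: 23, residue: R, group: active_site}
      - {position: 27, residue: F, group: active_site}
      - {position: 33, residue: W, group: active_site}
      - {position: 42, residue: E, group: active_site}
      - {position: 44, residue: D, group: active_site}
      - {position: 47, residue: D, group: active_site}
      - {position: 68, residue: R, group: active_site}
      - {position: 82, residue: F, group: active_site_conformation}
      - {position: 100, residue: E, group: active_site_conformation}
      - {position: 103, residue: R, group: active_site_conformation}
  luxr:
    role: LuxR
    reference_id: synthetic_luxr_reference
    reference_seq: >-
      KEMNFTGGCQPLHVTNPYCFEDKHTSYMLWQYNWDENNYRGWQDHPTCHRPNLDTDHMGL
      IWYYGYRGWCGGLTDPYDTPPQYEVCSEFWSITNYWNHEPQQVGSNQYVYLKGTYHNTVI
      DSICIFVPCFCGYQAGFHITLDWACTYWKQDPFVMMHDYIQKFVQPCCNQWTSCTWICTE
      GIMLFEIEKGQSATHSGHIHKKQEKIGMYGIEACALFMSHHAELHYTNFLFLDHANSEHV
    key_positions:
      - {position: 62, residue: W, group: autoinducer_binding}
      - {position: 66, residue: Y, group: autoinducer_binding}
      - {position: 75, residue: D, group: autoinducer_binding}
      - {position: 76, residue: P, group: autoinducer_binding}
      - {position: 90, residue: W, group: autoinducer_binding}
      - {position: 113, residue: G, group: autoinducer_binding}
      - {position: 180, residue: E, group: dna_binding}
      - {position: 184, residue: L, group: dna_binding}
      - {position: 190, residue: G, group: dna_binding}
  rpff:
    role: RpfF
    reference_id: synthetic_rpff_reference
    reference_seq: >-
      NHCFREMVMVHDCGNQPRTKELMRAKAYVHHDSGHCSWAPMEYALTKIHFQKAEQCEAVA
      NPKHHGTLHPIFGDAQWGPTKMWYCGWDREVYEQNNGHVEWAVTCLMYFAKVGEWYAEIF
      NLWMPELRQWSCKEESPGYQERGVDMRITCLGYEYMNAPSEYQDRQNVLFWWKRNSDGFR
      FSFVTNMCCPEKRVWHMPDMHDCRGLNMCKEALDLMNKWKHFANQKSMHPCYHRKPCQRG
      TSYGTQGFNTFHSWQSEWISEIAEIWWCRYKESNMMFQPDIIINWSPNCQPGWKCPPIRS
    key_positions:
      - {position: 86, residue: G, group: thioesterase}
      - {position: 138, residue: G, group: thioesterase}
      - {position: 141, residue: E, group: catalysis}
      - {position: 161, residue: E, group: catalysis}
  rpfb:
    role: RpfB
    reference_id: synthetic_rpfb_reference
    reference_seq: >-
      RTHQGFEDQIESHRIKYPFTICIMSSVTSFYLEIIGRSNNANYGLQHCVYAMPEQLDRRT
      IVMSYIGGDQDLIMAVNDPALGRIEGLVPLEIRIVPLLHDFLPRKSEYFKHTSPPCPQIY
      RGEKFGYRIWRGQIHSHVHYVSKRLGSGPIMRTMYKCKVPWQGNDYYWPLRHHKCCQMTD
      EVQKQFIKQGVDDMLKEGNIIHGVLIPIGGVSEPLSHHQEKFLTFCMYLLRQYWLTTLRC
      WNKKSQCELKHEYWPKQAYCKQSGRVHLQNPNQTEMIACTDTCDEPEEELTIHTFIKYWY
      SQSQVDYEFGFLEKSFHVRD
    # The active-site threonine/glutamate coordinates for this family are not
    # established for the packaged synthetic reference; the profile ships with
    # no key positions and the checker is a no-op until a user supplies them.
    key_positions: []
  ahld:
    role: AhlD
    reference_id: synthetic_ahld_reference
    reference_seq: >-
      IQYYRCQNMLGFRVENPQGIKPVSFFGGTIGNTMAMKPWTRSKPCTTKMKLFTSEKQKNQ
      RKARLQTNQQTQCKEQIGRGLPYEQPPVPVPIYECGTRRPEHSHLDHVGMMLESNGGWAP
      NTTCLETWNCSSIAIGNGMVCIMFWAQIPVINQAQCEGESNFRASYNYYQIFKPNTPGHT
      PGHWKTLGPCIYVMPSEYWGDYWKRQCTCNSRWWTWYLSAYMVVLAMSAIESPMSSQQLE
      WFMNATWRKQCLRYVYVFNK
    key_positions:
      - {position: 102, residue: H, group: zinc_coordination}
      - {position: 104, residue: H, group: zinc_coordination}
      - {position: 106, residue: D, group: zinc_coordination}
      - {position: 107, residue: H, group: zinc_coordination}
      - {position: 179, residue: H, group: zinc_coordination}
      - {position: 201, residue: D, group: zinc_coordination}
motifs:
  # Zinc-metallohydrolase signature of AHL lactonases: an HXHXDH block, a
  # downstream lone histidine, and a distal aspartate. The reference anchors
  # sit at 102, 179 and 201; spacer windows are the anchor-implied intervening
  # counts (71 and 21 residues) with a +/-10 tolerance. Set
  # `spacers: [[63, 63], [24, 24]]` to use literal spacer counts instead.
  ahld_zinc_hydrolase:
    kind: spaced
    blocks: [HXHXDH, H, D]
    spacers: [[61, 81], [11, 31]]
    max_mismatches: [0, 0, 0]
    anchor_positions: [102, 179, 201]
  # Lower-conservation tandem repeat inside the AhlD lactonase domain.
  ahld_tpgh:
    kind: block
    pattern: TPGHTPGH
    anchor_position: 176
    max_mismatches: 1
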