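{
 "_comment": "Synthetic demonstration-scale gene-symbol update map: classic spreadsheet-date-mangled families plus a few well-known renames. Not a complete nomenclature history; replace with a full versioned map for production use.",
 "alias_to_current": {
  "MARCH1": "MARCHF1",
  "MARCH2": "MARCHF2",
  "MARCH3": "MARCHF3",
  "MARCH4": "MARCHF4",
  "MARCH5": "MARCHF5",
  "MARCH6": "MARCHF6",
  "MARCH7": "MARCHF7",
  "MARCH8": "MARCHF8",
  "MARCH9": "MARCHF9",
  "MARCH10": "MARCHF10",
  "MARCH11": "MARCHF11",
  "SEPT1": "SEPTIN1",
  "SEPT2": "SEPTIN2",
  "SEPT3": "SEPTIN3",
  "SEPT4": "SEPTIN4",
  "SEPT5": "SEPTIN5",
  "SEPT6": "SEPTIN6",
  "SEPT7": "SEPTIN7",
  "SEPT8": "SEPTIN8",
  "SEPT9": "SEPTIN9",
  "SEPT10": "SEPTIN10",
  "SEPT11": "SEPTIN11",
  "SEPT12": "SEPTIN12",
  "SEPT14": "SEPTIN14",
  "DEC1": "DELEC1",
  "MARC1": "MTARC1",
  "MARC2": "MTARC2",
  "H2AFX": "H2AX",
  "HIST1H2BK": "H2BC12",
  "WHSC1": "NSD2",
  "KIAA1429": "VIRMA"
 },
 "date_repairs": {
  "3-Mar": "MARCH3",
  "4-Mar": "MARCH4",
  "5-Mar": "MARCH5",
  "6-Mar": "MARCH6",
  "7-Mar": "MARCH7",
  "8-Mar": "MARCH8",
  "9-Mar": "MARCH9",
  "10-Mar": "MARCH10",
  "11-Mar": "MARCH11",
  "3-Sep": "SEPT3",
  "4-Sep": "SEPT4",
  "5-Sep": "SEPT5",
  "6-Sep": "SEPT6",
  "7-Sep": "SEPT7",
  "8-Sep": "SEPT8",
  "9-Sep": "SEPT9",
  "10-Sep": "SEPT10",
  "11-Sep": "SEPT11",
  "12-Sep": "SEPT12",
  "14-Sep": "SEPT14",
  "1-Sep": "SEPT1",
  "2-Sep": "SEPT2",
  "1-Dec": "DEC1"
 },
 "ambiguous_dates": [
  "1-Mar",
  "2-Mar"
 ],
 "protected": [
  "MARCHF1", "MARCHF2", "MARCHF3", "MARCHF4", "MARCHF5", "MARCHF6",
  "MARCHF7", "MARCHF8", "MARCHF9", "MARCHF10", "MARCHF11",
  "SEPTIN1", "SEPTIN2", "SEPTIN3", "SEPTIN4", "SEPTIN5", "SEPTIN6",
  "SEPTIN7", "SEPTIN8", "SEPTIN9", "SEPTIN10", "SEPTIN11", "SEPTIN12",
  "SEPTIN14", "DELEC1", "MTARC1", "MTARC2", "H2AX", "H2BC12", "NSD2",
  "VIRMA", "EGR1", "FOS", "ARC", "RPS23", "BDNF", "CRH", "SST", "CCK"
 ]
}
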