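{
  "name": "hospital-admission",
  "enumerations": [
    {
      "name": "pCode",
      "literals": [
        "P012",
        "P047",
        "P103",
        "P215",
        "P330"
      ]
    },
    {
      "name": "dCode",
      "literals": [
        "Chickenpox",
        "Pneumonia",
        "Stroke",
        "Influenza",
        "Fracture"
      ]
    }
  ],
  "activities": [
    {
      "name": "Patient enters the hospital",
      "attributes": [
        {
          "name": "age",
          "type": "Integer"
        },
        {
          "name": "surname",
          "type": "String"
        },
        {
          "name": "total_expenses",
          "type": "Real"
        }
      ],
      "is_master": true
    },
    {
      "name": "Patient admitted to hospital ward",
      "attributes": []
    },
    {
      "name": "Patient sent home",
      "attributes": []
    },
    {
      "name": "Clinical process in ward",
      "attributes": []
    },
    {
      "name": "Doctor assigns procedure",
      "attributes": [
        {
          "name": "procedure_code",
          "type": "pCode"
        }
      ]
    },
    {
      "name": "Procedure is executed",
      "attributes": [
        {
          "name": "procedure_code",
          "type": "pCode"
        },
        {
          "name": "cost",
          "type": "Real"
        }
      ]
    },
    {
      "name": "Doctor sets diagnosis",
      "attributes": [
        {
          "name": "diagnosis",
          "type": "dCode"
        }
      ]
    },
    {
      "name": "Patient consulted by second doctor",
      "attributes": []
    },
    {
      "name": "Patient transferred to another ward",
      "attributes": []
    },
    {
      "name": "Patient discharged",
      "attributes": []
    }
  ],
  "edges": [
    {
      "kind": "follows",
      "source": "Patient enters the hospital",
      "target": "Patient admitted to hospital ward"
    },
    {
      "kind": "follows",
      "source": "Patient enters the hospital",
      "target": "Patient sent home"
    },
    {
      "kind": "follows",
      "source": "Patient admitted to hospital ward",
      "target": "Clinical process in ward"
    },
    {
      "kind": "composition",
      "source": "Clinical process in ward",
      "target": "Doctor assigns procedure",
      "cardinality": "*"
    },
    {
      "kind": "composition",
      "source": "Clinical process in ward",
      "target": "Procedure is executed",
      "cardinality": "*"
    },
    {
      "kind": "composition",
      "source": "Clinical process in ward",
      "target": "Doctor sets diagnosis",
      "cardinality": "*"
    },
    {
      "kind": "interruption",
      "source": "Clinical process in ward",
      "target": "Patient transferred to another ward"
    },
    {
      "kind": "interruption",
      "source": "Clinical process in ward",
      "target": "Patient discharged"
    },
    {
      "kind": "follows",
      "source": "Patient transferred to another ward",
      "target": "Patient discharged"
    },
    {
      "kind": "extension",
      "source": "Doctor sets diagnosis",
      "target": "Patient consulted by second doctor",
      "extension_point": "second opinion is necessary"
    }
  ]
}
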