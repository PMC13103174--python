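"""Shipped word lists backing the imprint content grammars.

These are small, seedable pools of plausible values — first/last names,
cities, hospitals, scanner models, exam types, diagnoses — not an attempt at
demographic realism. Users who need richer content can extend the taxonomy
via its YAML serialization instead of editing this module.
"""

FIRST_NAMES = [
    "John", "Jane", "Michael", "Emily", "David", "Sarah", "Robert", "Laura",
    "James", "Anna", "William", "Maria", "Thomas", "Linda", "Charles", "Karen",
    "Daniel", "Nancy", "Matthew", "Susan", "Anthony", "Margaret", "Mark",
    "Lisa", "Paul", "Sandra", "Steven", "Ashley", "Andrew", "Kimberly",
    "Joshua", "Donna", "Kevin", "Carol", "Brian", "Michelle", "George",
    "Amanda", "Edward", "Melissa", "Ronald", "Deborah", "Timothy", "Stephanie",
    "Jason", "Rebecca", "Jeffrey", "Sharon", "Ryan", "Cynthia", "Jacob",
    "Kathleen", "Gary", "Amy", "Nicholas", "Angela", "Eric", "Shirley",
    "Jonathan", "Brenda", "Stephen", "Emma", "Larry", "Pamela", "Justin",
    "Nicole", "Scott", "Helen", "Brandon", "Samantha", "Benjamin", "Katherine",
    "Samuel", "Christine", "Gregory", "Debra", "Alexander", "Rachel", "Frank",
    "Carolyn", "Patrick", "Janet", "Raymond", "Catherine", "Jack", "Ruth",
]

LAST_NAMES = [
    "Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller",
    "Davis", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez",
    "Wilson", "Anderson", "Thomas", "Taylor", "Moore", "Jackson", "Martin",
    "Lee", "Perez", "Thompson", "White", "Harris", "Sanchez", "Clark",
    "Ramirez", "Lewis", "Robinson", "Walker", "Young", "Allen", "King",
    "Wright", "Scott", "Torres", "Nguyen", "Hill", "Flores", "Green",
    "Adams", "Nelson", "Baker", "Hall", "Rivera", "Campbell", "Mitchell",
    "Carter", "Roberts", "Gomez", "Phillips", "Evans", "Turner", "Diaz",
    "Parker", "Cruz", "Edwards", "Collins", "Reyes", "Stewart", "Morris",
    "Morales", "Murphy", "Cook", "Rogers", "Gutierrez", "Ortiz", "Morgan",
    "Cooper", "Peterson", "Bailey", "Reed", "Kelly", "Howard", "Ramos",
    "Kim", "Cox", "Ward", "Richardson", "Watson", "Brooks", "Chavez",
]

STREET_NAMES = [
    "Main St", "Oak Ave", "Maple Dr", "Cedar Ln", "Park Ave", "Elm St",
    "Washington Blvd", "Lake Rd", "Hill St", "River Rd", "Sunset Blvd",
    "Pine St", "Church St", "High St", "Mill Rd", "Broadway", "Center St",
    "Franklin Ave", "Highland Ave", "Ridge Rd", "Forest Dr", "Spring St",
    "Jefferson Ave", "Lincoln St", "Madison Ave", "Valley Rd", "Grove St",
]

CITIES_STATES = [
    ("Springfield", "IL"), ("Columbus", "OH"), ("Austin", "TX"),
    ("Portland", "OR"), ("Madison", "WI"), ("Richmond", "VA"),
    ("Rochester", "MN"), ("Denver", "CO"), ("Phoenix", "AZ"),
    ("Atlanta", "GA"), ("Boston", "MA"), ("Seattle", "WA"),
    ("Nashville", "TN"), ("Charlotte", "NC"), ("Omaha", "NE"),
    ("Tucson", "AZ"), ("Fresno", "CA"), ("Raleigh", "NC"),
    ("Cleveland", "OH"), ("Tampa", "FL"), ("Pittsburgh", "PA"),
    ("Cincinnati", "OH"), ("Baltimore", "MD"), ("Milwaukee", "WI"),
    ("Albuquerque", "NM"), ("Sacramento", "CA"), ("Kansas City", "MO"),
]

COUNTRIES = ["USA", "United States", "US"]

EMAIL_DOMAINS = [
    "email.com", "mail.com", "example.com", "webmail.org", "inbox.net",
    "post.com", "mailbox.org", "fastmail.com",
]

HOSPITALS = [
    "Mayo Clinic Eau Claire", "St. Mary's Hospital", "General Hospital",
    "Mercy Medical Center", "University Hospital", "Memorial Hospital",
    "Sacred Heart Medical Center", "Riverside Community Hospital",
    "Lakeview Imaging Center", "Northside Radiology Associates",
    "County Medical Center", "Providence Health Center",
    "Baptist Medical Center", "Good Samaritan Hospital",
    "Children's Hospital", "Veterans Medical Center",
    "Regional Medical Center", "City Imaging Clinic",
    "Highland Park Hospital", "Westside Diagnostic Center",
    "Cedar Valley Clinic", "Summit Health Imaging",
    "Lakeshore Medical Imaging", "Metro Radiology Group",
]

SCANNERS = [
    "Philips Ingenia 3.0T", "Siemens MAGNETOM Vida 3T", "GE SIGNA Pioneer",
    "Canon Vantage Orian 1.5T", "Siemens SOMATOM Force", "GE Revolution CT",
    "Philips Brilliance 64", "Toshiba Aquilion ONE", "Siemens Biograph mCT",
    "GE Discovery MI", "Hologic Selenia Dimensions", "Fujifilm FDR Go",
    "Philips EPIQ Elite", "GE LOGIQ E10", "Siemens ACUSON Sequoia",
    "kVp 120 mAs 200", "TR 500 TE 15", "Slice 5.0mm", "FOV 350mm",
    "Pitch 0.8 Rot 0.5s", "B31s kernel", "WL 40 WW 400",
]

EXAM_TYPES = [
    "CT Cholangiography", "CT Abdomen Pelvis", "CT Chest w/o Contrast",
    "CT Head", "MRI Brain", "MRI Lumbar Spine", "MRI Knee",
    "Chest X-Ray PA", "Chest X-Ray Lateral", "Whole Body Bone Scan",
    "PET/CT Skull to Thigh", "Mammogram Screening", "Ultrasound Abdomen",
    "CT Angiography", "MRI Cervical Spine", "X-Ray Left Hand",
    "X-Ray Pelvis", "DEXA Scan", "CT Sinus", "MRI Shoulder",
    "Bone Scintigraphy", "CT Urogram", "MR Angiography Head",
]

DIAGNOSES = [
    "Fibrosis", "Pneumonia", "Pulmonary nodule", "Fracture left femur",
    "Degenerative disc disease", "Osteoarthritis", "Pleural effusion",
    "Cardiomegaly", "Atelectasis", "Emphysema", "No acute findings",
    "Cholelithiasis", "Hepatic steatosis", "Renal cyst", "Osteopenia",
    "Metastatic disease", "Normal study", "Chronic sinusitis",
    "Meniscal tear", "Disc herniation L4-L5", "Rotator cuff tear",
    "Compression fracture T12", "Followup recommended", "Clinical correlation advised",
]

MARKERS = [
    "L", "R", "POST", "ANT", "SUP", "INF", "LAT", "MED", "PA", "AP",
    "LEFT", "RIGHT", "SUPINE", "PRONE", "ERECT", "OBL",
]

PERSONNEL_ROLES = ["Dr.", "RT", "Tech.", ""]
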